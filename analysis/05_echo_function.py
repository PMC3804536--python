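"""Echocardiographic structure and function table.

Derives the body-weight-indexed dimensions, fractional shortening, diastolic
ratios and the Tei performance index per animal, summarises them by group
with significance marks, and prints the ratio-of-means cross-check so the
two summary conventions are both visible.  Run 01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

from myofame import echo
from myofame.stats import render_markdown, summary_table

OUT = Path("results/study")


def main() -> None:
    records = pd.read_csv(OUT / "inputs" / "echo.csv")
    indices = echo.derive_indices(records)
    indices.to_csv(OUT / "echo_indices.csv", index=False)
    table = summary_table(indices.drop(columns=["animal"]))
    md = render_markdown(table)
    (OUT / "echo_summary.md").write_text(md + "\n")
    print(md)
    print("\nratio-of-means cross-check (per-animal averaging is the headline):")
    print(echo.ratio_of_means_crosscheck(records).round(3).to_string(index=False))


if __name__ == "__main__":
    main()
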