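"""Group-level metabolic phenotype from the fitted endpoints.

Summarises MFAO/MFAE/MFAU, extraction fraction, MBF and MGU by group
(mean ± SD with pooled Student t-tests) and reports the GK/Wistar ratios
the study design encodes: a roughly two-fold oxidation increase despite
roughly halved blood flow, hence a near-doubled extraction fraction.
Run 02_fit_kinetics.py first.
"""

from pathlib import Path

import pandas as pd

from myofame.stats import percent_difference, render_markdown, summary_table

OUT = Path("results/study")
ENDPOINT_COLS = ["MFAO", "MFAE", "MFAU", "EF", "MBF", "MGU", "MFAOUpR", "MFAUUpR"]


def main() -> None:
    ep = pd.read_csv(OUT / "endpoints.csv")
    table = summary_table(ep[["group"] + ENDPOINT_COLS])
    md = render_markdown(table)
    (OUT / "metabolic_summary.md").write_text(md + "\n")
    print(md)

    means = ep.groupby("group")[ENDPOINT_COLS].mean()
    print("\nGK / Wistar group-mean ratios:")
    for col in ("MFAO", "MFAE", "MBF", "EF", "MGU"):
        ratio = means.loc["GK", col] / means.loc["Wistar", col]
        pct = percent_difference(means.loc["GK", col], means.loc["Wistar", col])
        print(f"  {col:>5}: ratio {ratio:.2f} ({pct:+d}%)")


if __name__ == "__main__":
    main()
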