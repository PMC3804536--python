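"""Differential expression of the diabetes and fatty-acid-metabolism arrays.

Normalises each 84-gene Ct table to the housekeeping trio, computes signed
fold changes and pooled-t significance tiers, counts significant genes per
array and direction, and clusters the significant genes (Spearman distance,
complete linkage) for the heat-map display.  Run 01_simulate_cohort.py first.
"""

from pathlib import Path

import pandas as pd

from myofame import qpcr

OUT = Path("results/study")
ARRAYS = {"diabetes": "qpcr_diabetes.csv", "fa_metabolism": "qpcr_fa_metabolism.csv"}


def main() -> None:
    qdir = OUT / "qpcr"
    qdir.mkdir(parents=True, exist_ok=True)
    for label, fname in ARRAYS.items():
        table = pd.read_csv(OUT / "inputs" / fname)
        de = qpcr.differential_expression(table)
        de.to_csv(qdir / f"{label}_results.csv", index=False)
        counts = qpcr.count_significant(de)
        print(
            f"{label} array: {counts['total']} significant genes "
            f"({counts['up']} up, {counts['down']} down in GK)"
        )
        top = de.reindex(de["fold_change"].abs().sort_values(ascending=False).index)
        print(top.head(5).round(3).to_string(index=False))

        sig = de.loc[de["p_value"] < 0.05, "gene"]
        expr = qpcr.expression_matrix(table).loc[sig]
        clust = qpcr.cluster_genes(expr)
        (qdir / f"{label}_dendrogram.nwk").write_text(clust.to_newick())
        qpcr.plot_heatmap(expr, clust, qdir / f"{label}_heatmap.png")
        print(f"  dendrogram and heat-map written under {qdir}\n")


if __name__ == "__main__":
    main()
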