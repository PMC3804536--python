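"""qPCR array differential expression: ddCt, fold change, t-tests, clustering.

Cycle-threshold (Ct) values from 84-gene arrays are normalised per replicate
against the mean of the three housekeeping genes (Rpl13a, Ldha, Actb):
dCt = Ct(gene) - mean(Ct(housekeeping)).  Group differences are expressed as
fold change 2^-(ddCt) with the signed convention used by array vendors: a
fold change below 1 is reported as -1/FC (so ddCt = +1 prints as -2, i.e.
2-fold down).  Significance is the classic equal-variance two-sample Student
t-test on per-replicate dCt values, annotated in tiers (* P<0.05, # P<0.01,
and the double-dagger for P<0.001).

Gene clustering for heat-map display uses Spearman correlation distance
(1 - rho across samples) with complete linkage.  The agglomeration is
implemented here rather than delegated, because reproducible dendrograms
need a deterministic tie-break (lexicographically smallest cluster labels
merge first), which library linkage routines do not expose; on matrices with
distinct distances it coincides with standard complete linkage.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, to_tree

HOUSEKEEPING_GENES = ("Actb", "Ldha", "Rpl13a")
CT_CEILING = 40.0  # "undetermined" wells are imputed at the cycle ceiling
SIGNIFICANCE_TIERS = ((0.001, "‡"), (0.01, "#"), (0.05, "*"))

REQUIRED_COLUMNS = ("gene", "gene_class", "group", "replicate", "ct")


def validate_ct_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check layout, impute undetermined wells at Ct=40, flag the imputations."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"Ct table is missing columns: {missing}")
    out = table.copy()
    undetermined = out["ct"].isna() | (out["ct"] > CT_CEILING)
    out["undetermined"] = undetermined
    out.loc[undetermined, "ct"] = CT_CEILING
    if (out["ct"] < 0).any():
        raise ValueError("Ct values must be non-negative")
    hk = out[out["gene_class"] == "housekeeping"]["gene"].unique()
    absent = set(HOUSEKEEPING_GENES) - set(hk)
    if absent:
        raise ValueError(f"housekeeping genes missing from table: {sorted(absent)}")
    return out


def delta_ct(table: pd.DataFrame) -> pd.DataFrame:
    """Per-well dCt against the replicate's mean housekeeping Ct.

    Returns the table with a ``dct`` column added for every non-housekeeping
    well.  Raises if any (group, replicate) lacks one of the housekeeping
    genes, naming the offender.
    """
    table = validate_ct_table(table)
    hk = table[table["gene"].isin(HOUSEKEEPING_GENES)]
    ref = hk.groupby(["group", "replicate"])["ct"].agg(["mean", "count"])
    bad = ref[ref["count"] < len(HOUSEKEEPING_GENES)]
    if len(bad):
        grp, rep = bad.index[0]
        raise ValueError(
            f"replicate {rep} of group {grp!r} lacks a housekeeping gene"
        )
    for grp, rep in (
        table[["group", "replicate"]].drop_duplicates().itertuples(index=False)
    ):
        if (grp, rep) not in ref.index:
            raise ValueError(
                f"replicate {rep} of group {grp!r} lacks a housekeeping gene"
            )
    out = table.merge(
        ref["mean"].rename("hk_mean"), left_on=["group", "replicate"], right_index=True
    )
    out["dct"] = out["ct"] - out["hk_mean"]
    return out


def fold_change(dct_test: np.ndarray, dct_reference: np.ndarray) -> float:
    """Signed fold change of the test group relative to the reference.

    FC_raw = 2^-(mean dCt_test - mean dCt_ref); reported as FC_raw when >= 1,
    else as -1/FC_raw, so |FC| >= 1 always and the sign carries direction.
    """
    ddct = float(np.mean(dct_test) - np.mean(dct_reference))
    raw = 2.0 ** (-ddct)
    return raw if raw >= 1.0 else -1.0 / raw


def significance_tier(p: float) -> str:
    for threshold, mark in SIGNIFICANCE_TIERS:
        if p < threshold:
            return mark
    return "ns"


def gene_ttest(dct_test: np.ndarray, dct_reference: np.ndarray) -> tuple[float, str]:
    """Two-sided equal-variance Student t-test on per-replicate dCt values."""
    a = np.asarray(dct_test, dtype=float)
    b = np.asarray(dct_reference, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 replicates per group")
    if np.var(a) == 0.0 and np.var(b) == 0.0:
        p = 1.0 if np.mean(a) == np.mean(b) else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=True).pvalue)
    return p, significance_tier(p)


def differential_expression(
    table: pd.DataFrame,
    test_group: str = "GK",
    reference_group: str = "Wistar",
    bh_correction: bool = False,
) -> pd.DataFrame:
    """Per-gene fold change, p-value and tier for all target genes.

    Benjamini-Hochberg adjusted q-values can be added, but the default
    reports nominal p-values in the vendor style.
    """
    dct = delta_ct(table)
    targets = dct[dct["gene_class"] == "target"]
    rows = []
    for gene, sub in targets.groupby("gene", sort=True):
        a = sub.loc[sub["group"] == test_group, "dct"].to_numpy()
        b = sub.loc[sub["group"] == reference_group, "dct"].to_numpy()
        fc = fold_change(a, b)
        p, tier = gene_ttest(a, b)
        rows.append({"gene": gene, "fold_change": fc, "p_value": p, "tier": tier})
    result = pd.DataFrame(rows)
    if bh_correction:
        result["q_value"] = stats.false_discovery_control(result["p_value"])
    return result


def count_significant(results: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Counts of significant genes split by direction of change."""
    sig = results[results["p_value"] < alpha]
    return {
        "up": int((sig["fold_change"] > 0).sum()),
        "down": int((sig["fold_change"] < 0).sum()),
        "total": int(len(sig)),
    }


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    genes: list[str]  # leaf names in linkage-id order (0..n-1)
    linkage: np.ndarray  # scipy-format (n-1, 4) merge table
    leaf_order: list[str]  # dendrogram display order

    def to_newick(self) -> str:
        tree = to_tree(self.linkage)

        def emit(node):
            if node.is_leaf():
                return self.genes[node.id]
            return f"({emit(node.left)},{emit(node.right)}):{node.dist:.6g}"

        left, right = tree.left, tree.right
        return f"({emit(left)},{emit(right)}):{tree.dist:.6g};"


def spearman_distance_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """d(g1, g2) = 1 - Spearman rho across samples; constant rows get d = 1."""
    if expr.shape[0] < 2:
        raise ValueError("need at least 2 genes to cluster")
    if expr.shape[1] < 3:
        raise ValueError("Spearman correlation needs at least 3 samples")
    ranks = np.apply_along_axis(stats.rankdata, 1, expr.to_numpy(dtype=float))
    with np.errstate(invalid="ignore"):
        rho = np.corrcoef(ranks)
    constant = np.ptp(expr.to_numpy(dtype=float), axis=1) == 0
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s): Spearman undefined, "
            "assigning unit distance",
            RuntimeWarning,
            stacklevel=2,
        )
    d = 1.0 - rho
    d[constant, :] = 1.0
    d[:, constant] = 1.0
    np.fill_diagonal(d, 0.0)
    return pd.DataFrame(d, index=expr.index, columns=expr.index)


def cluster_genes(expr: pd.DataFrame) -> ClusterResult:
    """Complete-linkage agglomeration on Spearman correlation distance.

    ``expr`` is a genes x samples matrix of per-replicate abundances (-dCt).
    Ties in the merge queue are broken by the lexicographically smallest pair
    of cluster labels (a cluster is labelled by its smallest member gene), so
    the dendrogram is reproducible.
    """
    expr = expr.sort_index()  # deterministic leaf ids
    genes = list(expr.index.astype(str))
    n = len(genes)
    dist = spearman_distance_matrix(expr).to_numpy()

    # active clusters: id -> (size, label); pair distances maintained by the
    # Lance-Williams complete-linkage update d(a+b, c) = max(d(a,c), d(b,c))
    clusters: dict[int, tuple[int, str]] = {i: (1, genes[i]) for i in range(n)}
    pairdist: dict[tuple[int, int], float] = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }

    Z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best = None
        for (ca, cb), d in pairdist.items():
            la, lb = sorted((clusters[ca][1], clusters[cb][1]))
            key = (d, la, lb)
            if best is None or key < best[0]:
                best = (key, ca, cb)
        (d, _, _), ca, cb = best
        size = clusters[ca][0] + clusters[cb][0]
        label = min(clusters[ca][1], clusters[cb][1])
        Z[step] = [min(ca, cb), max(ca, cb), d, size]
        others = [c for c in clusters if c not in (ca, cb)]
        for c in others:
            da = pairdist.pop((min(c, ca), max(c, ca)))
            db = pairdist.pop((min(c, cb), max(c, cb)))
            pairdist[(c, next_id)] = max(da, db)
        pairdist.pop((min(ca, cb), max(ca, cb)))
        del clusters[ca], clusters[cb]
        clusters[next_id] = (size, label)
        next_id += 1

    order = [genes[i] for i in leaves_list(Z)]
    return ClusterResult(genes=genes, linkage=Z, leaf_order=order)


def expression_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Genes x samples matrix of -dCt (abundance scale) for clustering/heat-maps."""
    dct = delta_ct(table)
    targets = dct[dct["gene_class"] == "target"].copy()
    targets["sample"] = targets["group"].astype(str) + "_" + targets["replicate"].astype(str)
    mat = targets.pivot_table(index="gene", columns="sample", values="dct")
    return -mat


def plot_heatmap(expr: pd.DataFrame, result: ClusterResult, path) -> None:
    """Clustered heat-map of per-replicate abundances (PNG/SVG by extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    ordered = expr.loc[result.leaf_order]
    fig, ax = plt.subplots(
        figsize=(0.35 * expr.shape[1] + 3, 0.18 * expr.shape[0] + 2)
    )
    im = ax.imshow(ordered.to_numpy(), aspect="auto", cmap="RdBu_r")
    ax.set_yticks(range(len(ordered.index)), ordered.index, fontsize=5)
    ax.set_xticks(range(len(ordered.columns)), ordered.columns, rotation=90, fontsize=6)
    fig.colorbar(im, ax=ax, label="-dCt (relative abundance)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
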