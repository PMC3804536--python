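"""qPCR engine tests: normalisation, fold change, t-tests, clustering oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps
from scipy.cluster.hierarchy import linkage

from myofame.qpcr import (
    cluster_genes,
    count_significant,
    delta_ct,
    differential_expression,
    expression_matrix,
    fold_change,
    gene_ttest,
    spearman_distance_matrix,
)
from myofame.simulate import make_qpcr_table


def _table(rows):
    return pd.DataFrame(rows, columns=["gene", "gene_class", "group", "replicate", "ct"])


def _hk_rows(group, rep, cts=(15.0, 16.0, 17.0)):
    return [
        (g, "housekeeping", group, rep, ct)
        for g, ct in zip(("Rpl13a", "Ldha", "Actb"), cts)
    ]


class TestDeltaCt:
    def test_gene_at_housekeeping_mean_has_zero_dct(self):
        rows = _hk_rows("GK", 1) + [("Gx", "target", "GK", 1, 16.0)]
        out = delta_ct(_table(rows))
        assert out.loc[out["gene"] == "Gx", "dct"].item() == pytest.approx(0.0)

    def test_arithmetic_example(self):
        # housekeeping (15, 16, 17), gene Ct 20 -> dCt = 4
        rows = _hk_rows("GK", 1) + [("Gx", "target", "GK", 1, 20.0)]
        out = delta_ct(_table(rows))
        assert out.loc[out["gene"] == "Gx", "dct"].item() == pytest.approx(4.0)

    def test_missing_housekeeping_gene_names_the_replicate(self):
        rows = (
            _hk_rows("GK", 1)
            + [("Gx", "target", "GK", 1, 20.0)]
            + _hk_rows("GK", 2)[:2]  # replicate 2 lacks Actb
            + [("Gx", "target", "GK", 2, 20.0)]
        )
        with pytest.raises(ValueError, match="replicate 2"):
            delta_ct(_table(rows))

    def test_known_shifts_round_trip(self):
        effects = {"Up1": -2.0, "Dn1": 1.5}
        table = make_qpcr_table(n_genes=10, effects=effects, seed=3, sigma_rep=0.0)
        dct = delta_ct(table)
        for gene, eff in effects.items():
            gk = dct.loc[(dct["gene"] == gene) & (dct["group"] == "GK"), "dct"].mean()
            w = dct.loc[(dct["gene"] == gene) & (dct["group"] == "Wistar"), "dct"].mean()
            assert gk - w == pytest.approx(eff, abs=1e-9)


class TestFoldChange:
    @pytest.mark.parametrize(
        "ddct,expected",
        [(0.0, 1.0), (-1.0, 2.0), (1.0, -2.0), (3.46, -11.004334545), (-3.46, 11.004334545)],
    )
    def test_signed_convention(self, ddct, expected):
        gk = np.array([5.0 + ddct] * 4)
        w = np.array([5.0] * 4)
        assert fold_change(gk, w) == pytest.approx(expected, rel=1e-9)

    def test_identity_on_equal_groups(self):
        a = np.array([1.3, 2.1, 0.7])
        assert fold_change(a, a) == pytest.approx(1.0)

    @settings(max_examples=50, deadline=None)
    @given(st.floats(min_value=-8, max_value=8))
    def test_sign_flip_inverts_and_magnitude_at_least_one(self, ddct):
        up = fold_change(np.array([ddct]), np.array([0.0]))
        dn = fold_change(np.array([-ddct]), np.array([0.0]))
        assert abs(up) >= 1.0
        assert up == pytest.approx(-1.0 / dn if dn != 0 else up, rel=1e-9) or (
            abs(up) == pytest.approx(abs(dn), rel=1e-9)
        )


class TestGeneTtest:
    def test_identical_groups_not_significant(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        p, tier = gene_ttest(a, a.copy())
        assert p == pytest.approx(1.0)
        assert tier == "ns"

    def test_matches_closed_form_pooled_t(self):
        # pooled-variance Student t: (1,2,3,4) vs (5,6,7,8) ->
        # t = -4/sqrt(sp2*(1/4+1/4)) = -4.38178, p = 0.0046592 (df = 6)
        p, tier = gene_ttest(np.array([1.0, 2, 3, 4]), np.array([5.0, 6, 7, 8]))
        assert p == pytest.approx(0.004659214944, rel=1e-9)
        assert tier == "#"

    def test_pooled_t_oracle_on_random_draws(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            n1, n2 = rng.integers(2, 8, size=2)
            a = rng.normal(0, 1, n1)
            b = rng.normal(0.5, 1.5, n2)
            p, _ = gene_ttest(a, b)
            sp2 = ((n1 - 1) * a.var(ddof=1) + (n2 - 1) * b.var(ddof=1)) / (n1 + n2 - 2)
            t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
            oracle = 2 * sps.t.sf(abs(t), n1 + n2 - 2)
            assert p == pytest.approx(oracle, rel=1e-10)

    def test_power_for_four_sd_effect(self):
        # effect of 4 replicate-SDs with n=4/group detected essentially always
        rng = np.random.default_rng(12)
        hits = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(0.0, 1.0, 4)
            b = rng.normal(4.0, 1.0, 4)
            p, _ = gene_ttest(a, b)
            hits += p < 0.05
        assert hits / n_sim > 0.95

    def test_degenerate_zero_variance(self):
        p, tier = gene_ttest(np.array([2.0, 2.0]), np.array([2.0, 2.0]))
        assert p == 1.0 and tier == "ns"


def brute_force_complete_linkage(dist: pd.DataFrame):
    """Independent O(n^3) complete-linkage oracle with the lexicographic tie-break."""
    names = list(dist.index)
    clusters = {i: frozenset([i]) for i in range(len(names))}
    merges = []
    next_id = len(names)
    while len(clusters) > 1:
        candidates = []
        for ca, cb in itertools.combinations(sorted(clusters), 2):
            d = max(
                dist.iloc[i, j] for i in clusters[ca] for j in clusters[cb]
            )
            la = min(names[i] for i in clusters[ca])
            lb = min(names[i] for i in clusters[cb])
            candidates.append(((d, *sorted((la, lb))), ca, cb))
        (d, _, _), ca, cb = min(candidates)
        merges.append((min(ca, cb), max(ca, cb), d, len(clusters[ca] | clusters[cb])))
        clusters[next_id] = clusters.pop(ca) | clusters.pop(cb)
        next_id += 1
    return merges


class TestClustering:
    def test_duplicated_rows_merge_first_at_zero_distance(self):
        expr = pd.DataFrame(
            [[1.0, 2, 3, 4], [1.0, 2, 3, 4], [4.0, 1, 3, 2]],
            index=["A", "B", "C"],
        )
        res = cluster_genes(expr)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert sorted(res.linkage[0, :2]) == [0.0, 1.0]  # leaves A and B

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        expr = pd.DataFrame(rng.normal(size=(5, 6)), index=list("ABCDE"))
        d1 = spearman_distance_matrix(expr)
        expr2 = expr.copy()
        expr2.loc["C"] = np.exp(expr2.loc["C"])  # strictly monotone
        d2 = spearman_distance_matrix(expr2)
        assert np.allclose(d1.to_numpy(), d2.to_numpy())

    def test_four_gene_toy_matrix_matches_brute_force(self):
        expr = pd.DataFrame(
            [[1, 2, 3, 4], [2, 3, 4, 5], [4, 3, 2, 1], [1, 3, 2, 4]],
            index=["g1", "g2", "g3", "g4"],
            dtype=float,
        )
        res = cluster_genes(expr)
        oracle = brute_force_complete_linkage(spearman_distance_matrix(expr.sort_index()))
        got = [(int(a), int(b), d, int(n)) for a, b, d, n in res.linkage]
        expect = [(a, b, pytest.approx(d, abs=1e-12), n) for a, b, d, n in oracle]
        assert got == expect

    @settings(max_examples=30, deadline=None)
    @given(
        n_genes=st.integers(min_value=2, max_value=6),
        seed=st.integers(min_value=0, max_value=10_000),
    )
    def test_matches_brute_force_on_small_matrices(self, n_genes, seed):
        rng = np.random.default_rng(seed)
        expr = pd.DataFrame(
            rng.integers(0, 5, size=(n_genes, 4)).astype(float),
            index=[f"g{i}" for i in range(n_genes)],
        )
        if (np.ptp(expr.to_numpy(), axis=1) == 0).any():
            expr.iloc[:, 0] += rng.normal(0, 0.01, n_genes)  # avoid constant rows
        res = cluster_genes(expr)
        oracle = brute_force_complete_linkage(spearman_distance_matrix(expr.sort_index()))
        for (a, b, d, n), row in zip(oracle, res.linkage):
            assert (int(row[0]), int(row[1]), int(row[3])) == (a, b, n)
            assert row[2] == pytest.approx(d, abs=1e-12)

    def test_agrees_with_scipy_when_distances_distinct(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.normal(size=(8, 14)), index=[f"g{i}" for i in range(8)])
        dist = spearman_distance_matrix(expr)
        condensed = dist.to_numpy()[np.triu_indices(8, k=1)]
        assert len(np.unique(condensed)) == len(condensed)  # no ties
        ours = cluster_genes(expr).linkage
        scipys = linkage(condensed, method="complete")
        assert np.allclose(np.sort(ours[:, 2]), np.sort(scipys[:, 2]))
        assert np.allclose(ours[:, 3], scipys[:, 3])

    def test_constant_row_warns_and_gets_unit_distance(self):
        expr = pd.DataFrame(
            [[1.0, 1, 1, 1], [1.0, 2, 3, 4], [2.0, 1, 4, 3]], index=["A", "B", "C"]
        )
        with pytest.warns(RuntimeWarning, match="constant"):
            d = spearman_distance_matrix(expr)
        assert d.loc["A", "B"] == 1.0 and d.loc["A", "C"] == 1.0

    def test_newick_export_contains_all_leaves(self):
        rng = np.random.default_rng(10)
        expr = pd.DataFrame(rng.normal(size=(5, 5)), index=list("ABCDE"))
        nwk = cluster_genes(expr).to_newick()
        assert nwk.endswith(";")
        for leaf in "ABCDE":
            assert leaf in nwk


class TestDifferentialExpression:
    def test_counts_and_direction_on_constructed_table(self):
        effects = {"Up1": -2.0, "Up2": -2.5, "Dn1": 2.0}
        table = make_qpcr_table(n_genes=8, effects=effects, seed=5, sigma_rep=0.05)
        de = differential_expression(table)
        counts = count_significant(de)
        assert counts["up"] >= 2
        assert counts["down"] >= 1
        up1 = de.set_index("gene").loc["Up1"]
        assert up1["fold_change"] == pytest.approx(4.0, rel=0.3)

    def test_all_null_pvalues_give_zero_at_alpha_zero(self):
        table = make_qpcr_table(n_genes=6, effects={}, seed=6)
        de = differential_expression(table)
        assert count_significant(de, alpha=0.0)["total"] == 0

    def test_bh_correction_column_optional(self):
        table = make_qpcr_table(n_genes=6, effects={}, seed=7)
        de = differential_expression(table, bh_correction=True)
        assert "q_value" in de.columns
        assert (de["q_value"] >= de["p_value"] - 1e-12).all()

    def test_expression_matrix_layout(self):
        table = make_qpcr_table(n_genes=5, effects={}, seed=8, n_per_group=3)
        mat = expression_matrix(table)
        assert mat.shape == (5, 6)  # genes x (2 groups * 3 replicates)
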