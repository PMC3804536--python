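"""Synthetic-data generator: reproducibility, noise model, regime construction."""

import dataclasses

import numpy as np
import pytest

from myofame.curves import TimeActivityCurve, frame_average
from myofame.fitting import palmitate_frame_tac
from myofame.simulate import (
    CohortSpec,
    default_regimes,
    diabetes_array_effects,
    fa_array_effects,
    make_echo_cohort,
    make_input_curve,
    make_palmitate_study,
    make_qpcr_table,
)
from myofame import reference


class TestInputCurve:
    def test_zero_dose_gives_zero_curve(self):
        assert np.all(make_input_curve(peak_value=0.0).concentration == 0.0)

    def test_fixed_seed_reproducible(self):
        a = make_input_curve(seed=5)
        b = make_input_curve(seed=5)
        assert np.array_equal(a.concentration, b.concentration)
        c = make_input_curve(seed=6)
        assert not np.array_equal(a.concentration, c.concentration)

    def test_peak_within_first_minute(self):
        curve = make_input_curve(seed=1)
        assert curve.times[np.argmax(curve.concentration)] <= 1.0

    def test_area_scales_linearly_with_dose(self):
        lo = make_input_curve(peak_value=50.0)
        hi = make_input_curve(peak_value=150.0)
        area = lambda c: np.trapezoid(c.concentration, c.times)
        assert area(hi) == pytest.approx(3 * area(lo), rel=1e-9)


@pytest.fixture(scope="module")
def studies():
    return make_palmitate_study(CohortSpec(seed=42))


class TestPalmitateStudy:
    def test_cohort_layout(self, studies):
        assert len(studies) == 8
        assert {s.group for s in studies} == {"GK", "Wistar"}

    def test_noiseless_tac_round_trips_through_forward_model(self, studies):
        s = studies[0]
        wbf = frame_average(
            s.truth_whole_blood.times, s.truth_whole_blood.concentration, s.frames
        )
        redo = palmitate_frame_tac(s.truth_params, s.truth_input, wbf, s.frames)
        assert np.allclose(redo, s.truth_extras["noiseless_tac"], rtol=1e-12)

    def test_truth_regime_mfao_ratio_is_two_by_construction(self):
        regimes = default_regimes()
        nefa = {
            g: reference.group_mean(reference.DESCRIPTIVE, "plasma_nefa_umol_per_L", g)
            for g in ("GK", "Wistar")
        }
        mfao = {
            g: regimes[g].palmitate.k1
            * nefa[g]
            * regimes[g].palmitate.oxidation_fraction
            for g in ("GK", "Wistar")
        }
        assert mfao["GK"] / mfao["Wistar"] == pytest.approx(2.0, rel=1e-12)

    def test_truth_regime_mbf_ratio_matches_published_scale(self):
        regimes = default_regimes()
        assert regimes["GK"].mbf / regimes["Wistar"].mbf == pytest.approx(
            2.46 / 4.32, rel=1e-12
        )

    def test_truth_regimes_live_in_the_canonical_ordering_chart(self):
        for regime in default_regimes().values():
            p = regime.palmitate
            assert p.k2 <= p.k3 + p.k4 <= p.k5

    def test_seeded_reproducibility(self):
        a = make_palmitate_study(CohortSpec(seed=7))[0]
        b = make_palmitate_study(CohortSpec(seed=7))[0]
        assert np.array_equal(a.tissue_tac.values, b.tissue_tac.values)
        assert a.truth_params == b.truth_params

    def test_count_noise_variance_model(self):
        # empirical variance of (noisy - noiseless) follows sigma^2 * C / dt
        spec = CohortSpec(seed=0)
        devs = []
        for rep_seed in range(60):
            s = make_palmitate_study(dataclasses.replace(spec, seed=rep_seed))[0]
            clean = s.truth_extras["noiseless_tac"]
            resid = (s.tissue_tac.values - clean) * np.sqrt(
                s.frames.durations / np.clip(clean, 1e-12, None)
            )
            devs.append(resid)
        sd = np.std(np.concatenate(devs))
        assert sd == pytest.approx(spec.noise_sigma, rel=0.05)

    def test_blood_samples_are_post_bolus_anchored(self, studies):
        s = studies[0]
        assert np.sum(s.blood_samples.times >= 5.0) >= 2
        assert s.blood_samples.parent_fraction is not None


class TestQpcrTable:
    def test_zero_effects_give_unit_fold_changes(self):
        from myofame.qpcr import differential_expression

        table = make_qpcr_table(n_genes=12, effects={}, seed=2, sigma_rep=0.05)
        de = differential_expression(table)
        assert np.all(np.abs(de["fold_change"]) < 1.3)

    def test_large_effect_reaches_eleven_fold(self):
        from myofame.qpcr import delta_ct, fold_change

        table = make_qpcr_table(
            n_genes=4, effects={"Retn": 3.46}, seed=3, sigma_rep=0.0
        )
        dct = delta_ct(table)
        sub = dct[dct["gene"] == "Retn"]
        fc = fold_change(
            sub.loc[sub["group"] == "GK", "dct"].to_numpy(),
            sub.loc[sub["group"] == "Wistar", "dct"].to_numpy(),
        )
        assert fc == pytest.approx(-11.0, abs=0.01)

    def test_seeded_reproducibility_and_housekeeping_presence(self):
        t1 = make_qpcr_table(seed=4, effects=diabetes_array_effects())
        t2 = make_qpcr_table(seed=4, effects=diabetes_array_effects())
        assert t1.equals(t2)
        hk = t1[t1["gene_class"] == "housekeeping"]["gene"].unique()
        assert set(hk) == {"Actb", "Ldha", "Rpl13a"}

    def test_effect_census_matches_published_hit_counts(self):
        assert len(diabetes_array_effects()) == 17
        fa = fa_array_effects()
        assert len(fa) == 41
        assert all(v < 0 for v in fa.values())  # all up-regulated in GK


class TestEchoCohort:
    def test_zero_spread_reproduces_published_group_means(self):
        from myofame.echo import derive_indices

        idx = derive_indices(make_echo_cohort(n_per_group=2, seed=5, sd_scale=0.0))
        w = idx[idx["group"] == "Wistar"].iloc[0]
        assert w["Tei Index"] == pytest.approx(0.489, abs=0.001)
        assert w["FS (%)"] == pytest.approx(43.34, abs=0.01)

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_echo_cohort(n_per_group=0)

    def test_reproducible(self):
        assert make_echo_cohort(seed=9).equals(make_echo_cohort(seed=9))
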