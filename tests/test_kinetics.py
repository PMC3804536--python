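"""Forward-solver tests against independent oracles and model invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from myofame.curves import DomainError, FrameSchedule, InputFunction, TimeActivityCurve, frame_average
from myofame.kinetics import (
    FdgParams,
    OneTissueParams,
    PalmitateParams,
    measured_tac,
    patlak_slope,
    solve_fdg,
    solve_one_tissue,
    solve_palmitate,
    spillover_correct,
)
from myofame.simulate import make_input_curve

# Frozen oracle values for the unit-step input, k = (0.5, 0.2, 0.1, 0.3, 0.05),
# computed from the augmented matrix exponential expm([[A, b], [0, 0]] * 10)
# (independently cross-checked with solve_ivp at rtol 1e-12).
STEP_T10_EXPECTED = np.array([2.16166179, 0.93455634, 0.47594547, 1.22527355])


def _ivp_reference(params: PalmitateParams, cp, t_end, times):
    A = np.array(
        [
            [-params.k2, 0, 0, 0],
            [params.k2, -(params.k3 + params.k4), 0, 0],
            [0, params.k3, 0, 0],
            [0, params.k4, 0, -params.k5],
        ]
    )
    sol = solve_ivp(
        lambda t, x: A @ x + np.array([params.k1 * cp(t), 0, 0, 0]),
        (0.0, t_end),
        np.zeros(4),
        t_eval=times,
        rtol=1e-11,
        atol=1e-13,
        max_step=0.05,
    )
    return sol.y


class TestPalmitateSolver:
    def test_zero_input_gives_zero_compartments(self, frames):
        zero = InputFunction(np.array([0.0, 20.0]), np.array([0.0, 0.0]))
        sol = solve_palmitate(PalmitateParams(0.5, 0.2, 0.1, 0.3, 0.05), zero, frames.mids)
        assert np.all(sol.total == 0.0)

    def test_absent_esterification_pathway(self, bolus_input):
        sol = solve_palmitate(
            PalmitateParams(0.5, 0.2, 0.0, 0.3, 0.05), bolus_input, [5.0, 10.0]
        )
        assert np.all(sol.C3 == 0.0)

    def test_step_input_matches_matrix_exponential_oracle(self, step_input):
        sol = solve_palmitate(
            PalmitateParams(0.5, 0.2, 0.1, 0.3, 0.05), step_input, [10.0]
        )
        got = np.array([sol.C1[0], sol.C2[0], sol.C3[0], sol.C4[0]])
        assert got == pytest.approx(STEP_T10_EXPECTED, rel=1e-7)

    def test_exponential_basis_and_expm_paths_agree(self, bolus_input):
        p = PalmitateParams(0.8, 0.4, 0.15, 0.3, 0.5, 0.2)
        t = np.linspace(0.5, 19.5, 30)
        a = solve_palmitate(p, bolus_input, t, method="expconv")
        b = solve_palmitate(p, bolus_input, t, method="expm")
        assert np.allclose(a.total, b.total, rtol=1e-10, atol=1e-12)

    @settings(max_examples=20, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_agreement_with_ode_oracle_on_random_draws(self, seed):
        rng = np.random.default_rng(seed)
        p = PalmitateParams(*rng.uniform(0.05, 2.0, size=5))
        cp = make_input_curve(seed=int(rng.integers(1e6)))
        t = np.linspace(0.5, 19.5, 15)
        sol = solve_palmitate(p, cp, t)
        ref = _ivp_reference(p, cp, 19.5, t)
        scale = np.max(ref.sum(axis=0))
        assert np.max(np.abs(sol.total - ref.sum(axis=0))) <= 1e-6 * scale

    def test_linearity_in_input_amplitude(self, bolus_input):
        p = PalmitateParams(0.7, 0.35, 0.12, 0.25, 0.4)
        t = np.linspace(1.0, 19.0, 10)
        one = solve_palmitate(p, bolus_input, t)
        two = solve_palmitate(p, bolus_input.scaled(2.0), t)
        assert np.allclose(two.total, 2 * one.total, rtol=1e-12)

    def test_mass_balance_without_washout(self, bolus_input):
        # with k5 = 0 nothing leaves the tissue: total = k1 * integral of Cp
        p = PalmitateParams(0.7, 0.35, 0.12, 0.25, 0.0)
        t = np.array([5.0, 10.0, 19.0])
        sol = solve_palmitate(p, bolus_input, t)
        expect = p.k1 * bolus_input.cumulative_integral(t)
        assert np.allclose(sol.total, expect, rtol=1e-9)

    @settings(max_examples=15, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_non_negative_curves_for_non_negative_input(self, seed):
        rng = np.random.default_rng(seed)
        p = PalmitateParams(*rng.uniform(0.0, 3.0, size=5))
        cp = make_input_curve(seed=seed)
        sol = solve_palmitate(p, cp, np.linspace(0.1, 19.9, 50))
        for c in (sol.C1, sol.C2, sol.C3, sol.C4):
            assert np.all(c >= -1e-12)

    def test_negative_rate_constant_rejected(self):
        with pytest.raises(ValueError):
            PalmitateParams(0.5, -0.2, 0.1, 0.3, 0.05)

    def test_times_outside_input_support_rejected(self, bolus_input):
        p = PalmitateParams(0.5, 0.2, 0.1, 0.3, 0.05)
        with pytest.raises(DomainError):
            solve_palmitate(p, bolus_input, [25.0])


class TestOneTissue:
    def test_zero_uptake_gives_zero(self, bolus_input):
        ct = solve_one_tissue(OneTissueParams(0.0, 1.0), bolus_input, [5.0, 10.0])
        assert np.all(ct == 0.0)

    def test_pure_accumulation_with_constant_input(self, step_input):
        # k2 = 0 and Cp = c: Ct(t) = K1 * c * t
        ct = solve_one_tissue(OneTissueParams(2.0, 0.0), step_input, [1.0, 5.0, 10.0])
        assert ct == pytest.approx([2.0, 10.0, 20.0], rel=1e-12)

    def test_matches_convolution_quadrature_oracle(self, bolus_input):
        K1, k2, t_eval = 3.0, 1.2, 5.0
        ct = solve_one_tissue(OneTissueParams(K1, k2), bolus_input, [t_eval])[0]
        tt = np.linspace(0.0, t_eval, 200001)
        oracle = K1 * np.trapezoid(bolus_input(tt) * np.exp(-k2 * (t_eval - tt)), tt)
        assert ct == pytest.approx(oracle, rel=1e-7)


class TestMeasuredTac:
    def _constant_world(self, frames):
        t = np.linspace(0.0, 20.0, 401)
        curves = solve_palmitate(
            PalmitateParams(0, 0, 0, 0, 0), InputFunction([0, 20], [0, 0]), t
        )
        # overwrite with constant compartments summing to 2 kBq/g
        curves.C1 = np.full_like(t, 2.0)
        curves.C2 = np.zeros_like(t)
        curves.C3 = np.zeros_like(t)
        curves.C4 = np.zeros_like(t)
        blood = InputFunction(np.array([0.0, 20.0]), np.array([10.0, 10.0]))
        return curves, blood

    def test_convex_combination_of_tissue_and_blood(self, frames):
        curves, blood = self._constant_world(frames)
        tac = measured_tac(curves, blood, 0.3, frames)
        assert np.allclose(tac.values, 0.7 * 2.0 + 0.3 * 10.0)

    def test_no_spillover_returns_tissue_sum(self, frames):
        curves, blood = self._constant_world(frames)
        assert np.allclose(measured_tac(curves, blood, 0.0, frames).values, 2.0)

    def test_pure_blood_roi(self, frames):
        curves, blood = self._constant_world(frames)
        assert np.allclose(measured_tac(curves, blood, 1.0, frames).values, 10.0)

    def test_short_curves_rejected(self, frames, bolus_input):
        short = solve_palmitate(
            PalmitateParams(0.5, 0.2, 0.1, 0.3, 0.05), bolus_input, np.linspace(0, 10, 50)
        )
        with pytest.raises(DomainError):
            measured_tac(short, bolus_input, 0.3, frames)


class TestSpilloverCorrect:
    def test_inverts_the_mixing(self, frames):
        tissue = np.linspace(0.0, 30.0, 40)
        blood = np.linspace(50.0, 5.0, 40)
        mixed = TimeActivityCurve(frames, 0.7 * tissue + 0.3 * blood, units="kBq/g")
        rec = spillover_correct(mixed, blood, 0.3)
        assert np.allclose(rec.values, tissue)

    def test_pure_blood_fraction_rejected(self, frames):
        tac = TimeActivityCurve(frames, np.ones(40))
        with pytest.raises(ValueError):
            spillover_correct(tac, np.ones(40), 1.0)


class TestPatlak:
    def test_exact_line_recovered(self, frames, bolus_input):
        # construct tissue values exactly on a Patlak line with slope 0.05
        mids = frames.mids
        cp = bolus_input(mids)
        x = bolus_input.cumulative_integral(mids) / cp
        tissue = TimeActivityCurve(frames, (0.05 * x + 0.2) * cp, units="kBq/g")
        fit = patlak_slope(tissue, bolus_input, t_star=7.5)
        assert fit.slope == pytest.approx(0.05, rel=1e-9)
        assert fit.intercept == pytest.approx(0.2, rel=1e-9)

    def test_irreversible_two_tissue_ki_asymptote(self, frames, bolus_input):
        p = FdgParams(K1=0.6, k2=0.9, k3=0.3)
        assert p.Ki == pytest.approx(0.15)
        ct = solve_fdg(p, bolus_input, bolus_input.times)
        tac = TimeActivityCurve(
            frames, frame_average(bolus_input.times, ct, frames), units="kBq/g"
        )
        fit = patlak_slope(tac, bolus_input, t_star=10.0)
        assert fit.slope == pytest.approx(p.Ki, rel=0.05)

    def test_zero_tissue_gives_zero_slope(self, frames, bolus_input):
        tac = TimeActivityCurve(frames, np.zeros(40), units="kBq/g")
        fit = patlak_slope(tac, bolus_input, t_star=7.5)
        assert fit.slope == pytest.approx(0.0, abs=1e-15)

    def test_too_few_late_frames_rejected(self, frames, bolus_input):
        tac = TimeActivityCurve(frames, np.ones(40), units="kBq/g")
        with pytest.raises(ValueError):
            patlak_slope(tac, bolus_input, t_star=19.0)


class TestFdgParams:
    def test_ki_never_exceeds_k1(self):
        p = FdgParams(K1=0.6, k2=0.9, k3=0.3)
        assert p.Ki <= p.K1
        assert FdgParams(K1=0.6, k2=0.0, k3=0.0).Ki == 0.0
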