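"""Compartment models for [11C]palmitate, [11C]acetate and FDG kinetics.

The palmitate model is a five-compartment, six-parameter configuration:
plasma (Cp) feeds an extracellular pool C1 at k1 (mL/g/min); C1 transfers to
a cytosolic pool C2 at k2 (1/min); C2 branches into an esterified pool C3 at
k3 and an oxidized pool C4 at k4; C4 clears as [11C]CO2 at k5.  The sixth
parameter f_bv is the blood-volume / spillover fraction mixing the blood-pool
signal into the myocardial region of interest::

    dC1/dt = k1*Cp - k2*C1
    dC2/dt = k2*C1 - (k3 + k4)*C2
    dC3/dt = k3*C2
    dC4/dt = k4*C2 - k5*C4

All compartments start empty.  Because the system is linear and lower
triangular, its solution for a piecewise-linear input is a linear combination
of exponential convolutions E_lam(t) = ∫ Cp(s) exp(-lam (t-s)) ds, each of
which has an exact per-segment recursion.  That exponential-basis path is the
default solver; an augmented matrix-exponential propagator (also exact for
piecewise-linear forcing) backs it up when eigenvalues nearly coincide and
the partial-fraction weights would lose precision.

The acetate flow model is the one-tissue reduction (K1, k2), and FDG uses the
irreversible two-tissue model (K1, k2, k3) whose net-uptake constant is
Ki = K1*k3/(k2+k3); Patlak graphical analysis estimates Ki directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .curves import DomainError, FrameSchedule, InputFunction, TimeActivityCurve, frame_average

__all__ = [
    "PalmitateParams",
    "OneTissueParams",
    "FdgParams",
    "CompartmentCurves",
    "PatlakFit",
    "solve_palmitate",
    "solve_one_tissue",
    "solve_fdg",
    "measured_tac",
    "patlak_slope",
]

# eigenvalue gap (1/min) below which partial fractions defer to the
# matrix-exponential propagator
_DEGENERACY_GAP = 1e-6


def _check_nonneg(value: float, name: str) -> float:
    value = float(value)
    if not np.isfinite(value) or value < 0:
        raise ValueError(f"{name} must be a finite non-negative number, got {value}")
    return value


def _check_fraction(value: float, name: str) -> float:
    value = float(value)
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"{name} must lie in [0, 1], got {value}")
    return value


@dataclass(frozen=True)
class PalmitateParams:
    """Rate constants of the palmitate model plus the spillover fraction."""

    k1: float  # mL/g/min, plasma -> extracellular uptake
    k2: float  # 1/min, extracellular -> cytosolic
    k3: float  # 1/min, cytosolic -> esterified
    k4: float  # 1/min, cytosolic -> oxidized
    k5: float  # 1/min, [11C]CO2 washout
    f_bv: float = 0.0  # unitless blood-volume/spillover fraction

    def __post_init__(self):
        for name in ("k1", "k2", "k3", "k4", "k5"):
            _check_nonneg(getattr(self, name), name)
        _check_fraction(self.f_bv, "f_bv")

    @property
    def oxidation_fraction(self) -> float:
        """k4/(k3+k4): share of utilized fatty acid routed to oxidation."""
        if self.k3 + self.k4 == 0:
            raise ValueError("oxidation fraction undefined when k3 = k4 = 0")
        return self.k4 / (self.k3 + self.k4)

    def as_array(self) -> np.ndarray:
        return np.array([self.k1, self.k2, self.k3, self.k4, self.k5, self.f_bv])


@dataclass(frozen=True)
class OneTissueParams:
    """One-tissue model (acetate flow surrogate)."""

    K1: float  # mL/g/min
    k2: float  # 1/min
    f_bv: float = 0.0

    def __post_init__(self):
        _check_nonneg(self.K1, "K1")
        _check_nonneg(self.k2, "k2")
        _check_fraction(self.f_bv, "f_bv")

    def as_array(self) -> np.ndarray:
        return np.array([self.K1, self.k2, self.f_bv])


@dataclass(frozen=True)
class FdgParams:
    """Irreversible two-tissue FDG model."""

    K1: float  # mL/g/min
    k2: float  # 1/min
    k3: float  # 1/min
    f_bv: float = 0.0

    def __post_init__(self):
        _check_nonneg(self.K1, "K1")
        _check_nonneg(self.k2, "k2")
        _check_nonneg(self.k3, "k3")
        _check_fraction(self.f_bv, "f_bv")

    @property
    def Ki(self) -> float:
        """Net uptake constant K1*k3/(k2+k3) (mL/g/min); Ki <= K1."""
        if self.k2 + self.k3 == 0:
            return 0.0
        return self.K1 * self.k3 / (self.k2 + self.k3)


@dataclass
class CompartmentCurves:
    """Tissue compartment concentrations on a common time grid (kBq/g)."""

    times: np.ndarray
    C1: np.ndarray
    C2: np.ndarray
    C3: np.ndarray
    C4: np.ndarray

    @property
    def total(self) -> np.ndarray:
        return self.C1 + self.C2 + self.C3 + self.C4


@dataclass(frozen=True)
class PatlakFit:
    slope: float  # Ki, mL/g/min
    intercept: float
    n_frames_used: int


# ---------------------------------------------------------------------------
# exact building blocks


def exp_conv(times: np.ndarray, values: np.ndarray, lam: float) -> np.ndarray:
    """y(t_i) = ∫₀^{t_i} f(s)·exp(-lam·(t_i - s)) ds for piecewise-linear f.

    Exact per segment: with f(s) = f_i + m·s on a step of width h,
    the update is y ← y·e^{-lam h} + f_i·I0 + m·I1 where
    I0 = (1 - e^{-lam h})/lam and I1 = (h - I0)/lam.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    h = np.diff(times)
    if np.any(h <= 0):
        raise ValueError("times must be strictly increasing")
    if lam < 0:
        raise ValueError("decay rate must be non-negative")
    if lam == 0.0:
        seg = h * (values[1:] + values[:-1]) / 2.0
        return np.concatenate([[0.0], np.cumsum(seg)])
    decay = np.exp(-lam * h)
    i0 = -np.expm1(-lam * h) / lam
    small = lam * h < 1e-4  # series avoids cancellation in (h - I0)/lam
    i1 = np.where(
        small,
        h * h / 2.0 - lam * h**3 / 6.0 + lam * lam * h**4 / 24.0,
        (h - i0) / np.where(small, 1.0, lam),
    )
    slope = np.diff(values) / h
    incr = values[:-1] * i0 + slope * i1
    out = np.empty(times.size)
    out[0] = 0.0
    acc = 0.0
    # plain-float recursion: the only inherently sequential part
    for i, (d, b) in enumerate(zip(decay.tolist(), incr.tolist())):
        acc = acc * d + b
        out[i + 1] = acc
    return out


def _multi_exp_conv_weights(lams: np.ndarray) -> np.ndarray:
    """Partial-fraction weights of e^{-l1 t} ⊗ … ⊗ e^{-ln t} over basis E_li."""
    n = lams.size
    weights = np.empty(n)
    for i in range(n):
        others = np.delete(lams, i)
        weights[i] = 1.0 / np.prod(others - lams[i])
    return weights


def _min_gap(lams) -> float:
    lams = np.sort(np.asarray(lams, dtype=float))
    return float(np.min(np.diff(lams))) if lams.size > 1 else np.inf


def _solver_grid(input_fn: InputFunction, times: np.ndarray) -> np.ndarray:
    times = np.atleast_1d(np.asarray(times, dtype=float))
    if times.size == 0:
        raise ValueError("times must be non-empty")
    if np.any(times < 0) or np.any(times > input_fn.t_max + 1e-9):
        raise DomainError(
            f"requested times outside the input support [0, {input_fn.t_max:g}] min"
        )
    knots = input_fn.times[input_fn.times <= np.max(times) + 1e-12]
    grid = np.union1d(np.union1d(knots, times), [0.0, float(np.max(times))])
    return grid


def _propagate_expm(A: np.ndarray, b_scale: float, grid: np.ndarray,
                    forcing: np.ndarray) -> np.ndarray:
    """Exact states of dx/dt = A x + b_scale*forcing(t)*e1, piecewise-linear forcing.

    Augments the state with the forcing value and its per-segment slope so one
    matrix exponential per unique step width propagates everything exactly.
    """
    n = A.shape[0]
    M = np.zeros((n + 2, n + 2))
    M[:n, :n] = A
    M[0, n] = b_scale
    M[n, n + 1] = 1.0
    h = np.diff(grid)
    slopes = np.diff(forcing) / h
    cache: dict[float, np.ndarray] = {}
    x = np.zeros(n)
    out = np.zeros((grid.size, n))
    for i in range(h.size):
        key = round(float(h[i]), 12)
        phi = cache.get(key)
        if phi is None:
            phi = expm(M * h[i])
            cache[key] = phi
        z = np.concatenate([x, [forcing[i], slopes[i]]])
        x = phi[:n] @ z
        out[i + 1] = x
    return out


def _palmitate_matrix(p: PalmitateParams) -> np.ndarray:
    kappa = p.k3 + p.k4
    return np.array(
        [
            [-p.k2, 0.0, 0.0, 0.0],
            [p.k2, -kappa, 0.0, 0.0],
            [0.0, p.k3, 0.0, 0.0],
            [0.0, p.k4, 0.0, -p.k5],
        ]
    )


# ---------------------------------------------------------------------------
# forward solvers


def solve_palmitate(
    params: PalmitateParams,
    input_fn: InputFunction,
    times,
    method: str = "auto",
) -> CompartmentCurves:
    """Forward-solve the palmitate compartment system on the requested grid.

    ``method`` selects the solution path: ``"expconv"`` (exponential-basis
    partial fractions), ``"expm"`` (augmented matrix-exponential stepping) or
    ``"auto"`` which uses the former unless eigenvalues nearly coincide.
    Both are exact for the piecewise-linear input contract, so they agree to
    rounding; the option exists for cross-checking.
    """
    if not isinstance(params, PalmitateParams):
        params = PalmitateParams(*params)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    grid = _solver_grid(input_fn, times)
    cp = input_fn(grid)

    kappa = params.k3 + params.k4
    lam_sets = [
        (params.k2, kappa),
        (params.k2, kappa, 0.0),
        (params.k2, kappa, params.k5),
    ]
    degenerate = any(_min_gap(s) < _DEGENERACY_GAP for s in lam_sets)
    if method == "expm" or (method == "auto" and degenerate):
        states = _propagate_expm(_palmitate_matrix(params), params.k1, grid, cp)
        c1, c2, c3, c4 = states.T
    elif method in ("auto", "expconv"):
        if method == "expconv" and degenerate:
            raise ValueError("near-coincident rate constants: use method='expm'")
        cache: dict[float, np.ndarray] = {}

        def E(lam: float) -> np.ndarray:
            if lam not in cache:
                cache[lam] = exp_conv(grid, cp, lam)
            return cache[lam]

        def conv(coef: float, lams: tuple) -> np.ndarray:
            if coef == 0.0:
                return np.zeros(grid.size)
            lams_arr = np.asarray(lams, dtype=float)
            w = _multi_exp_conv_weights(lams_arr)
            return coef * sum(wi * E(li) for wi, li in zip(w, lams_arr))

        c1 = params.k1 * E(params.k2)
        if params.k2 == 0.0:
            c2 = c3 = c4 = np.zeros(grid.size)
        else:
            c2 = conv(params.k1 * params.k2, (params.k2, kappa))
            c3 = conv(params.k1 * params.k2 * params.k3, (params.k2, kappa, 0.0))
            c4 = conv(params.k1 * params.k2 * params.k4, (params.k2, kappa, params.k5))
    else:
        raise ValueError(f"unknown method {method!r}")

    idx = np.searchsorted(grid, times)
    return CompartmentCurves(times, c1[idx], c2[idx], c3[idx], c4[idx])


def solve_one_tissue(
    params: OneTissueParams, input_fn: InputFunction, times
) -> np.ndarray:
    """Ct(t) = K1·∫ Cp(s)·exp(-k2 (t-s)) ds on the requested grid."""
    if not isinstance(params, OneTissueParams):
        params = OneTissueParams(*params)
    times = np.atleast_1d(np.asarray(times, dtype=float))
    grid = _solver_grid(input_fn, times)
    ct = params.K1 * exp_conv(grid, input_fn(grid), params.k2)
    return ct[np.searchsorted(grid, times)]


def solve_fdg(params: FdgParams, input_fn: InputFunction, times) -> np.ndarray:
    """Total tissue activity C1+C2 of the irreversible two-tissue FDG model."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    grid = _solver_grid(input_fn, times)
    cp = input_fn(grid)
    loss = params.k2 + params.k3
    c1 = params.K1 * exp_conv(grid, cp, loss)
    if params.k3 == 0.0:
        c2 = np.zeros(grid.size)
    elif loss < _DEGENERACY_GAP:
        # k2 = k3 = 0: C1 integrates Cp, C2 stays empty
        c2 = np.zeros(grid.size)
    else:
        w = _multi_exp_conv_weights(np.array([loss, 0.0]))
        c2 = params.K1 * params.k3 * (
            w[0] * exp_conv(grid, cp, loss) + w[1] * exp_conv(grid, cp, 0.0)
        )
    total = c1 + c2
    return total[np.searchsorted(grid, times)]


def measured_tac(
    curves: CompartmentCurves,
    blood: InputFunction,
    f_bv: float,
    frames: FrameSchedule,
) -> TimeActivityCurve:
    """Frame-averaged model TAC with blood-volume spillover.

    Returns the frame integral of (1-f_bv)·(C1+C2+C3+C4) + f_bv·Cblood divided
    by the frame duration — PET frames integrate activity, they do not sample
    it at mid-frame.
    """
    f_bv = _check_fraction(f_bv, "f_bv")
    grid = curves.times
    if grid[-1] < frames.ends[-1] - 1e-9:
        raise DomainError("compartment curves do not cover the frame schedule")
    total = (1.0 - f_bv) * curves.total + f_bv * blood(grid)
    return TimeActivityCurve(frames, frame_average(grid, total, frames), units="kBq/g")


def spillover_correct(
    tissue: TimeActivityCurve, blood_frames: np.ndarray, f_bv: float
) -> TimeActivityCurve:
    """Remove a known blood-volume fraction from a measured myocardial TAC.

    Inverts the spillover mixing: C_tissue = (TAC - f_bv*C_blood)/(1 - f_bv).
    Used ahead of graphical analyses that assume a pure tissue curve (Patlak
    would otherwise report (1 - f_bv)*Ki, since the blood term only shifts
    the intercept).
    """
    f_bv = _check_fraction(f_bv, "f_bv")
    if f_bv == 1.0:
        raise ValueError("cannot recover tissue signal from a pure-blood ROI")
    blood_frames = np.asarray(blood_frames, dtype=float)
    if blood_frames.size != tissue.frames.n_frames:
        raise ValueError("blood values must match the tissue frame schedule")
    corrected = (tissue.values - f_bv * blood_frames) / (1.0 - f_bv)
    return TimeActivityCurve(tissue.frames, corrected, units=tissue.units)


def patlak_slope(
    tissue: TimeActivityCurve, input_fn: InputFunction, t_star: float = 7.5
) -> PatlakFit:
    """Patlak graphical analysis of an irreversible tracer (FDG).

    Regresses Ct(t)/Cp(t) on ∫₀ᵗCp/Cp(t) over frames with mid-time ≥ t_star;
    the slope is the net uptake constant Ki (mL/g/min).
    """
    mids = tissue.times
    use = mids >= t_star
    if int(np.sum(use)) < 3:
        raise ValueError(
            f"Patlak needs at least 3 frames after t* = {t_star:g} min, "
            f"found {int(np.sum(use))}"
        )
    t = mids[use]
    cp = input_fn(t)
    if np.any(cp <= 0):
        raise ValueError("plasma concentration must be positive on Patlak frames")
    x = input_fn.cumulative_integral(t) / cp
    y = tissue.values[use] / cp
    slope, intercept = np.polyfit(x, y, 1)
    return PatlakFit(float(slope), float(intercept), int(np.sum(use)))
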