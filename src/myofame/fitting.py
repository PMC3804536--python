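"""Weighted nonlinear least-squares estimation of kinetic rate constants.

The estimator minimises

    sum_f  w_f * (TAC_f - model_f(theta))^2,
    w_f = dt_f / max(C_f, eps),

the standard count-statistics weighting for frame-averaged PET data (longer
frames and lower counts are less noisy per becquerel).  ``model_f`` is the
frame-averaged forward solution including the blood-volume spillover term.
Six-parameter fits have local minima, so the optimiser restarts from
log-uniformly perturbed initial values (default 5 starts, seeded) and keeps
the best solution.  Only frames fully inside the fit window (default the
first 15 minutes of the 20-minute acquisition) enter the objective.

A structural point shapes the palmitate estimator: the total-tissue TAC is
exactly invariant under permutations of the three tissue eigenvalues
(k2, k3+k4, k5) with compensating adjustments of the k3/k4 branch — only
k1, f_bv, the oxidation fraction k4/(k3+k4) and the eigenvalue *set* are
identifiable from the measured signal.  As is standard for models with
exchangeable components (multi-exponential decays, mixtures), the fit is
performed in an order-constrained chart k2 <= k3+k4 <= k5 that selects one
canonical representative of each equivalence class; reported rate constants
are to be read under that convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .curves import FrameSchedule, InputFunction, TimeActivityCurve
from .kinetics import OneTissueParams, PalmitateParams, solve_one_tissue, solve_palmitate

__all__ = [
    "FitConfig",
    "FitResult",
    "fit_palmitate",
    "fit_one_tissue",
    "palmitate_frame_tac",
    "one_tissue_frame_tac",
]

# palmitate fit runs in the order-constrained chart
# (k1, k2, d_kappa = (k3+k4)-k2, d_k5 = k5-(k3+k4), phi = k4/(k3+k4), f_bv)
PALMITATE_BOUNDS = {
    "k1": (0.0, 20.0),
    "k2": (0.0, 10.0),
    "d_kappa": (0.0, 10.0),
    "d_k5": (0.0, 10.0),
    "phi": (0.0, 1.0),
    "f_bv": (0.0, 1.0),
}
PALMITATE_INIT = {
    "k1": 1.0, "k2": 0.25, "d_kappa": 0.1, "d_k5": 0.1, "phi": 0.5, "f_bv": 0.2,
}
_PALMITATE_FRACTIONS = ("phi", "f_bv")  # jittered uniformly, not log-scaled


def _palmitate_from_chart(x) -> PalmitateParams:
    k1, k2, d_kappa, d_k5, phi, f_bv = x
    kappa = k2 + d_kappa
    return PalmitateParams(
        k1=k1, k2=k2, k3=(1.0 - phi) * kappa, k4=phi * kappa,
        k5=kappa + d_k5, f_bv=f_bv,
    )


ONE_TISSUE_BOUNDS = {"K1": (0.0, 20.0), "k2": (0.0, 10.0), "f_bv": (0.0, 1.0)}
ONE_TISSUE_INIT = {"K1": 2.0, "k2": 1.0, "f_bv": 0.2}
_ONE_TISSUE_FRACTIONS = ("f_bv",)


@dataclass(frozen=True)
class FitConfig:
    """Options controlling the weighted NLLS fit."""

    fit_window: tuple[float, float] = (0.0, 15.0)  # minutes
    weight_floor_fraction: float = 0.01  # eps = fraction * max(TAC)
    restarts: int = 5
    seed: int = 0
    max_nfev: int = 600
    xtol: float = 1e-10
    ftol: float = 1e-10
    init: dict = field(default_factory=dict)  # per-parameter overrides
    bounds: dict = field(default_factory=dict)
    frame_subdivision: int = 4  # solver-grid points per frame interior

    def __post_init__(self):
        if self.fit_window[1] <= self.fit_window[0]:
            raise ValueError("fit window must have positive length")
        if self.restarts < 1:
            raise ValueError("need at least one start")


@dataclass
class FitResult:
    """Estimates plus fit diagnostics."""

    estimates: PalmitateParams | OneTissueParams
    rss: float
    stderr: dict
    converged: bool
    n_frames_used: int
    n_starts: int
    best_start: int

    def as_dict(self) -> dict:
        est = {
            name: float(getattr(self.estimates, name))
            for name in self.estimates.__dataclass_fields__
        }
        return {
            "estimates": est,
            "rss": self.rss,
            "stderr": self.stderr,
            "converged": self.converged,
            "n_frames_used": self.n_frames_used,
            "n_starts": self.n_starts,
            "best_start": self.best_start,
        }


# ---------------------------------------------------------------------------
# forward model on the frame schedule


def _eval_grid(input_fn: InputFunction, frames: FrameSchedule, n_sub: int) -> np.ndarray:
    """Solver grid: input knots plus frame edges plus interior refinement."""
    end = min(frames.ends[-1], input_fn.t_max)
    pieces = [input_fn.times[input_fn.times <= end + 1e-12], frames.starts, [end]]
    ends = frames.ends[frames.ends <= end + 1e-9]
    pieces.append(ends)
    for k in range(1, n_sub + 1):
        pieces.append(frames.starts + frames.durations * k / (n_sub + 1))
    grid = np.union1d(np.concatenate([np.atleast_1d(p) for p in pieces]), [0.0])
    return grid[grid <= end + 1e-12]


def _frame_weight_matrix(grid: np.ndarray, frames: FrameSchedule) -> np.ndarray:
    """Rows of trapezoid weights so that W @ values = frame averages.

    Requires the grid to contain every frame edge (guaranteed by _eval_grid).
    """
    W = np.zeros((frames.n_frames, grid.size))
    for f, (a, b) in enumerate(zip(frames.starts, frames.ends)):
        i0 = int(np.searchsorted(grid, a - 1e-12))
        i1 = int(np.searchsorted(grid, b - 1e-12))
        seg = grid[i0 : i1 + 1]
        if seg.size < 2 or abs(seg[0] - a) > 1e-9 or abs(seg[-1] - b) > 1e-9:
            raise ValueError("solver grid does not contain the frame edges")
        h = np.diff(seg)
        w = np.zeros(seg.size)
        w[:-1] += h / 2.0
        w[1:] += h / 2.0
        W[f, i0 : i1 + 1] = w / (b - a)
    return W


def palmitate_frame_tac(
    params: PalmitateParams,
    plasma: InputFunction,
    whole_blood_frames: np.ndarray,
    frames: FrameSchedule,
    n_sub: int = 4,
) -> np.ndarray:
    """Frame-averaged palmitate model TAC with spillover from frame-averaged blood."""
    grid = _eval_grid(plasma, frames, n_sub)
    curves = solve_palmitate(params, plasma, grid)
    W = _frame_weight_matrix(grid, frames)
    return (1.0 - params.f_bv) * (W @ curves.total) + params.f_bv * np.asarray(
        whole_blood_frames, dtype=float
    )


def one_tissue_frame_tac(
    params: OneTissueParams,
    plasma: InputFunction,
    whole_blood_frames: np.ndarray,
    frames: FrameSchedule,
    n_sub: int = 4,
) -> np.ndarray:
    grid = _eval_grid(plasma, frames, n_sub)
    ct = solve_one_tissue(params, plasma, grid)
    W = _frame_weight_matrix(grid, frames)
    return (1.0 - params.f_bv) * (W @ ct) + params.f_bv * np.asarray(
        whole_blood_frames, dtype=float
    )


# ---------------------------------------------------------------------------
# the estimator


def _window_mask(frames: FrameSchedule, window) -> np.ndarray:
    return (frames.starts >= window[0] - 1e-9) & (frames.ends <= window[1] + 1e-9)


def _restrict_to_window(
    tissue: TimeActivityCurve, whole_blood: np.ndarray, blood: InputFunction, cfg: FitConfig
) -> tuple[TimeActivityCurve, np.ndarray]:
    """Keep frames fully inside the fit window and the input-function support."""
    frames = tissue.frames
    end = min(cfg.fit_window[1], blood.t_max)
    mask = _window_mask(frames, (cfg.fit_window[0], end))
    if not mask.any():
        raise ValueError(f"no frames inside fit window {cfg.fit_window}")
    sub = FrameSchedule(frames.starts[mask], frames.durations[mask])
    return (
        TimeActivityCurve(sub, tissue.values[mask], units=tissue.units),
        whole_blood[mask],
    )


def _run_fit(
    names: list[str],
    make_params,
    model_fn,
    tissue: TimeActivityCurve,
    cfg: FitConfig,
    bounds_default: dict,
    init_default: dict,
    min_frames: int,
    fractions: tuple = (),
) -> FitResult:
    data = tissue.values
    if np.allclose(data, 0.0):
        raise ValueError("degenerate all-zero tissue TAC")
    frames = tissue.frames
    use = _window_mask(frames, cfg.fit_window)
    n_used = int(np.sum(use))
    if n_used < min_frames:
        raise ValueError(
            f"only {n_used} frames inside fit window {cfg.fit_window}, "
            f"need >= {min_frames}"
        )
    eps = cfg.weight_floor_fraction * float(np.max(np.abs(data)))
    w = frames.durations[use] / np.maximum(data[use], eps)
    sqrt_w = np.sqrt(w)
    y = data[use]

    bounds = {**bounds_default, **cfg.bounds}
    init = {**init_default, **cfg.init}
    lo = np.array([bounds[n][0] for n in names])
    hi = np.array([bounds[n][1] for n in names])
    x0_base = np.clip(np.array([init[n] for n in names]), lo + 1e-9, hi - 1e-9)

    def residuals(x):
        params = make_params(x)
        model = model_fn(params)[use]
        return sqrt_w * (model - y)

    rng = np.random.default_rng(cfg.seed)
    best = None
    best_start = -1
    any_converged = False
    for start in range(cfg.restarts):
        x0 = x0_base.copy()
        if start > 0:
            jitter = np.exp(rng.uniform(np.log(1 / 3), np.log(3), size=len(names)))
            x0 = x0_base * jitter
            for frac in fractions:
                x0[names.index(frac)] = rng.uniform(0.05, 0.9)
            x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        sol = least_squares(
            residuals,
            x0,
            bounds=(lo, hi),
            method="trf",
            x_scale="jac",
            xtol=cfg.xtol,
            ftol=cfg.ftol,
            gtol=1e-12,
            max_nfev=cfg.max_nfev,
        )
        ok = sol.status > 0
        any_converged = any_converged or ok
        if best is None or sol.cost < best.cost:
            best = sol
            best_start = start

    rss = float(2.0 * best.cost)
    dof = max(n_used - len(names), 1)
    jtj = best.jac.T @ best.jac
    cov = np.linalg.pinv(jtj) * (rss / dof)
    stderr = {n: float(np.sqrt(max(cov[i, i], 0.0))) for i, n in enumerate(names)}
    return FitResult(
        estimates=make_params(best.x),
        rss=rss,
        stderr=stderr,
        converged=bool(any_converged),
        n_frames_used=n_used,
        n_starts=cfg.restarts,
        best_start=best_start,
    )


def fit_palmitate(
    tissue: TimeActivityCurve,
    blood: InputFunction,
    whole_blood: TimeActivityCurve,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Estimate (k1..k5, f_bv) from a myocardial TAC.

    ``blood`` is the calibrated, metabolite-corrected plasma input driving the
    compartments; ``whole_blood`` is the uncorrected blood-pool TAC feeding the
    spillover term.
    """
    cfg = cfg or FitConfig()
    if whole_blood.values.size != tissue.frames.n_frames:
        raise ValueError("tissue and whole-blood TACs must share the frame schedule")
    tissue, wb = _restrict_to_window(tissue, whole_blood.values, blood, cfg)
    frames = tissue.frames

    def model_fn(params: PalmitateParams) -> np.ndarray:
        return palmitate_frame_tac(params, blood, wb, frames, cfg.frame_subdivision)

    names = ["k1", "k2", "d_kappa", "d_k5", "phi", "f_bv"]
    return _run_fit(
        names,
        _palmitate_from_chart,
        model_fn,
        tissue,
        cfg,
        PALMITATE_BOUNDS,
        PALMITATE_INIT,
        min_frames=10,
        fractions=_PALMITATE_FRACTIONS,
    )


def fit_one_tissue(
    tissue: TimeActivityCurve,
    blood: InputFunction,
    whole_blood: TimeActivityCurve,
    cfg: FitConfig | None = None,
) -> FitResult:
    """Estimate (K1, k2, f_bv) of the one-tissue (acetate flow) model."""
    cfg = cfg or FitConfig()
    if whole_blood.values.size != tissue.frames.n_frames:
        raise ValueError("tissue and whole-blood TACs must share the frame schedule")
    tissue, wb = _restrict_to_window(tissue, whole_blood.values, blood, cfg)
    frames = tissue.frames

    def model_fn(params: OneTissueParams) -> np.ndarray:
        return one_tissue_frame_tac(params, blood, wb, frames, cfg.frame_subdivision)

    names = ["K1", "k2", "f_bv"]
    return _run_fit(
        names,
        lambda x: OneTissueParams(*x),
        model_fn,
        tissue,
        cfg,
        ONE_TISSUE_BOUNDS,
        ONE_TISSUE_INIT,
        min_frames=6,
        fractions=_ONE_TISSUE_FRACTIONS,
    )
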