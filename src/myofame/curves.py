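"""Frame-timed activity curves and plasma input functions.

Dynamic PET data come in two temporal flavours.  Reconstructed images and
region-of-interest read-outs are *frame averaged*: each value is the mean
activity concentration over a finite acquisition frame.  Arterial input
functions, by contrast, are treated as continuous curves known at sample
points and interpolated linearly in between.  The two containers here keep
that distinction explicit so the kinetic code never has to guess.

Units follow the conventions of small-animal cardiac PET: time in minutes,
blood activity in kBq/mL, tissue activity in kBq/g.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class DomainError(ValueError):
    """Raised when a curve is evaluated outside its temporal support."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite values")
    return arr


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (minutes) of contiguous acquisition frames."""

    starts: np.ndarray
    durations: np.ndarray

    def __post_init__(self):
        starts = _as_float_array(self.starts, "starts")
        durations = _as_float_array(self.durations, "durations")
        if starts.size == 0:
            raise ValueError("frame schedule must contain at least one frame")
        if starts.size != durations.size:
            raise ValueError("starts and durations must have equal length")
        if np.any(durations <= 0):
            raise ValueError("frame durations must be positive")
        if np.any(np.diff(starts) <= 0):
            raise ValueError("frame starts must be strictly increasing")
        ends = starts + durations
        if np.any(starts[1:] < ends[:-1] - 1e-9):
            raise ValueError("frames must not overlap")
        object.__setattr__(self, "starts", starts)
        object.__setattr__(self, "durations", durations)

    @property
    def ends(self) -> np.ndarray:
        return self.starts + self.durations

    @property
    def mids(self) -> np.ndarray:
        return self.starts + 0.5 * self.durations

    @property
    def n_frames(self) -> int:
        return self.starts.size

    @property
    def span(self) -> float:
        return float(self.ends[-1])

    @classmethod
    def default(cls) -> "FrameSchedule":
        """Default 40-frame / 20-minute schedule: 24x5 s, 8x15 s, 8x120 s."""
        durations = np.concatenate(
            [np.full(24, 5.0), np.full(8, 15.0), np.full(8, 120.0)]
        ) / 60.0
        starts = np.concatenate([[0.0], np.cumsum(durations)[:-1]])
        return cls(starts, durations)


@dataclass
class TimeActivityCurve:
    """One activity value per frame for a single region.

    ``values`` are frame-averaged activity concentrations; ``units`` records
    whether the region is blood ("kBq/mL") or tissue ("kBq/g").
    """

    frames: FrameSchedule
    values: np.ndarray
    units: str = "kBq/mL"

    def __post_init__(self):
        self.values = _as_float_array(self.values, "values")
        if self.values.size != self.frames.n_frames:
            raise ValueError(
                f"{self.values.size} values for {self.frames.n_frames} frames"
            )

    @property
    def times(self) -> np.ndarray:
        """Frame mid-times, the natural abscissa for plotting and Patlak."""
        return self.frames.mids

    def to_frame(self) -> pd.DataFrame:
        col = "activity_kBq_per_mL" if self.units == "kBq/mL" else "activity_kBq_per_g"
        return pd.DataFrame(
            {
                "frame_start_min": self.frames.starts,
                "frame_duration_min": self.frames.durations,
                col: self.values,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "TimeActivityCurve":
        df = pd.read_csv(path)
        value_cols = [c for c in df.columns if c.startswith("activity_")]
        if len(value_cols) != 1:
            raise ValueError(f"expected one activity column, found {value_cols}")
        units = "kBq/mL" if value_cols[0].endswith("mL") else "kBq/g"
        frames = FrameSchedule(
            df["frame_start_min"].to_numpy(), df["frame_duration_min"].to_numpy()
        )
        return cls(frames, df[value_cols[0]].to_numpy(), units=units)

    def as_input_function(self) -> "InputFunction":
        """Piecewise-linear view through the frame mid-points (blood curves)."""
        return InputFunction(self.times, np.clip(self.values, 0.0, None))


@dataclass
class InputFunction:
    """Plasma (or whole-blood) tracer concentration versus time.

    Piecewise linear between samples, identically zero before the first
    sample, undefined past the last one.  This is the forcing term of every
    compartment model in :mod:`myofame.kinetics`.
    """

    times: np.ndarray
    concentration: np.ndarray
    units: str = "kBq/mL"

    def __post_init__(self):
        self.times = _as_float_array(self.times, "times")
        self.concentration = _as_float_array(self.concentration, "concentration")
        if self.times.size != self.concentration.size:
            raise ValueError("times and concentration must have equal length")
        if self.times.size < 2:
            raise ValueError("input function needs at least two samples")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times[0] < 0:
            raise ValueError("times must be non-negative")
        if np.any(self.concentration < 0):
            raise ValueError("concentrations must be non-negative")

    @property
    def t_max(self) -> float:
        return float(self.times[-1])

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t > self.t_max + 1e-9) or np.any(t < 0):
            raise DomainError(
                f"input function defined on [0, {self.t_max:g}] min, "
                f"requested up to {float(np.max(t)):g}"
            )
        out = np.interp(t, self.times, self.concentration, left=0.0)
        return out

    def cumulative_integral(self, t) -> np.ndarray:
        """∫₀ᵗ Cp(s) ds by exact trapezoid on the piecewise-linear curve."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        knots = np.union1d(self.times, t)
        knots = knots[(knots >= 0) & (knots <= self.t_max + 1e-12)]
        if self.times[0] > 0:
            knots = np.union1d(knots, [0.0])
        vals = self(knots)
        cum = np.concatenate([[0.0], np.cumsum(np.diff(knots) * (vals[1:] + vals[:-1]) / 2.0)])
        return np.interp(t, knots, cum)

    def scaled(self, factor: float) -> "InputFunction":
        if factor < 0:
            raise ValueError("scale factor must be non-negative")
        return InputFunction(self.times.copy(), self.concentration * factor, self.units)

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"time_min": self.times, "activity_kBq_per_mL": self.concentration}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "InputFunction":
        df = pd.read_csv(path)
        return cls(df["time_min"].to_numpy(), df["activity_kBq_per_mL"].to_numpy())


def frame_average(times: np.ndarray, values: np.ndarray, frames: FrameSchedule) -> np.ndarray:
    """Average a continuous curve over each frame interval.

    ``values`` is the curve sampled on the strictly increasing grid ``times``;
    the curve is treated as piecewise linear, so the trapezoid rule is exact.
    Frame edges need not be grid points: edge values are interpolated.
    """
    times = _as_float_array(times, "times")
    values = _as_float_array(values, "values")
    if times.size != values.size:
        raise ValueError("times and values must have equal length")
    if frames.starts[0] < times[0] - 1e-9 or frames.ends[-1] > times[-1] + 1e-9:
        raise DomainError("frame schedule extends beyond the sampled grid")
    out = np.empty(frames.n_frames)
    for i, (a, b) in enumerate(zip(frames.starts, frames.ends)):
        sub = times[(times > a) & (times < b)]
        grid = np.concatenate([[a], sub, [b]])
        v = np.interp(grid, times, values)
        out[i] = np.trapezoid(v, grid) / (b - a)
    return out
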