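"""Hybrid image/blood-sample input functions with metabolite correction.

The image-derived input function (IDIF) read from the LV blood-pool ROI has
the right shape but an uncertain absolute scale (partial volume, calibration).
A handful of discrete whole-blood samples drawn during the scan anchor the
scale: the IDIF is multiplied by the single least-squares factor matching the
image curve to the samples.  For 11C tracers the circulating activity is
progressively contaminated by labelled metabolites, so the calibrated curve
is further multiplied by a parent-fraction model

    f_parent(t) = (1 - a)·exp(-b·t) + a,

a monoexponential decline to a plateau ``a`` — f_parent(0) = 1 and the
correction never increases activity.  FDG is metabolite-stable and skips
this step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curves import InputFunction, TimeActivityCurve

__all__ = [
    "BloodSampleSet",
    "MetaboliteModel",
    "calibrate_idif",
    "metabolite_correct",
    "fit_parent_fraction",
]

# samples later than this (minutes) count as post-bolus anchors for calibration
LATE_SAMPLE_CUTOFF = 5.0


@dataclass
class BloodSampleSet:
    """Discrete whole-blood samples drawn during the scan (typically 5-6)."""

    times: np.ndarray
    whole_blood_activity: np.ndarray  # kBq/mL
    parent_fraction: np.ndarray | None = None  # unitless in [0, 1]

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.whole_blood_activity = np.asarray(self.whole_blood_activity, dtype=float)
        if self.times.size != self.whole_blood_activity.size:
            raise ValueError("times and activities must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if np.any(self.whole_blood_activity < 0):
            raise ValueError("activities must be non-negative")
        if self.parent_fraction is not None:
            self.parent_fraction = np.asarray(self.parent_fraction, dtype=float)
            if self.parent_fraction.size != self.times.size:
                raise ValueError("parent_fraction must match sample count")
            if np.any((self.parent_fraction < 0) | (self.parent_fraction > 1)):
                raise ValueError("parent fractions must lie in [0, 1]")

    def to_csv(self, path) -> None:
        data = {
            "time_min": self.times,
            "activity_kBq_per_mL": self.whole_blood_activity,
        }
        if self.parent_fraction is not None:
            data["parent_fraction"] = self.parent_fraction
        pd.DataFrame(data).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "BloodSampleSet":
        df = pd.read_csv(path)
        pf = df["parent_fraction"].to_numpy() if "parent_fraction" in df else None
        return cls(df["time_min"].to_numpy(), df["activity_kBq_per_mL"].to_numpy(), pf)


@dataclass(frozen=True)
class MetaboliteModel:
    """Monoexponential-to-plateau parent fraction f(t) = (1-a)·e^{-b t} + a."""

    a: float  # plateau fraction in [0, 1]
    b: float  # 1/min

    def __post_init__(self):
        if not 0.0 <= self.a <= 1.0:
            raise ValueError(f"plateau fraction a must lie in [0, 1], got {self.a}")
        if self.b < 0:
            raise ValueError(f"decay rate b must be non-negative, got {self.b}")

    def parent_fraction(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return (1.0 - self.a) * np.exp(-self.b * t) + self.a


def calibrate_idif(
    image_blood: TimeActivityCurve | InputFunction, samples: BloodSampleSet
) -> tuple[InputFunction, float]:
    """Scale the image-derived blood curve to the discrete blood samples.

    The factor is the least-squares ratio sum(img·sample)/sum(img²) evaluated
    at the sample times, i.e. a single global rescaling — 5-6 samples cannot
    constrain anything richer.  Returns the calibrated curve and the factor.
    """
    curve = (
        image_blood.as_input_function()
        if isinstance(image_blood, TimeActivityCurve)
        else image_blood
    )
    n_late = int(np.sum(samples.times >= LATE_SAMPLE_CUTOFF))
    if n_late < 2:
        raise ValueError(
            f"need at least 2 blood samples at t >= {LATE_SAMPLE_CUTOFF:g} min "
            f"(past the bolus peak), found {n_late}"
        )
    img = curve(samples.times)
    denom = float(np.dot(img, img))
    if denom == 0.0:
        raise ValueError("image curve is zero at all sample times; cannot calibrate")
    factor = float(np.dot(img, samples.whole_blood_activity)) / denom
    if factor <= 0:
        raise ValueError(f"non-positive calibration factor {factor}")
    return curve.scaled(factor), factor


def metabolite_correct(input_fn: InputFunction, model: MetaboliteModel) -> InputFunction:
    """Pointwise product of the input curve with the parent fraction."""
    corrected = input_fn.concentration * model.parent_fraction(input_fn.times)
    return InputFunction(input_fn.times.copy(), corrected, input_fn.units)


def fit_parent_fraction(samples: BloodSampleSet) -> MetaboliteModel:
    """Least-squares fit of the (a, b) parent-fraction model to measured fractions."""
    if samples.parent_fraction is None:
        raise ValueError("samples carry no parent_fraction measurements")
    t = samples.times
    f = samples.parent_fraction
    if t.size < 3:
        raise ValueError(f"need at least 3 parent-fraction samples, got {t.size}")
    if np.allclose(f, 1.0):
        return MetaboliteModel(a=1.0, b=0.0)  # no metabolism; b unidentifiable

    def resid(theta):
        a, b = theta
        return (1.0 - a) * np.exp(-b * t) + a - f

    sol = least_squares(
        resid, x0=[float(np.clip(f[-1], 0.0, 1.0)), 0.1],
        bounds=([0.0, 0.0], [1.0, 20.0]),
    )
    a, b = sol.x
    return MetaboliteModel(a=float(a), b=float(b))
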