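"""Physiological endpoints derived from fitted rate constants.

Extrinsic rates couple the heart's kinetic capacity to the circulating
substrate level:

    MFAU = k1 * [NEFA]                      total fatty-acid utilization
    MFAO = MFAU * k4 / (k3 + k4)            oxidation share
    MFAE = MFAU * k3 / (k3 + k4)            esterification share

with [NEFA] in nmol/mL (numerically equal to umol/L), so mL/g/min times
nmol/mL gives nmol/g/min.  Intrinsic (UpR) rates are the same quantities at
unit plasma concentration — the heart's capacity independent of substrate
supply — hence extrinsic = intrinsic x [NEFA] exactly, and MFAO + MFAE = MFAU
by construction.

Myocardial blood flow comes from the acetate one-tissue uptake constant
corrected by a fixed first-pass extraction (MBF = K1/E, default E = 0.63),
and glucose utilization from the FDG Patlak slope via the lumped constant
(MGU = Ki*[glucose]/LC, default LC = 0.67).  The fatty-acid extraction
fraction normalises uptake to flow: EF = k1/MBF.
"""

from __future__ import annotations

from dataclasses import dataclass

from .kinetics import OneTissueParams, PalmitateParams

DEFAULT_ACETATE_EXTRACTION = 0.63  # first-pass extraction of [11C]acetate
DEFAULT_LUMPED_CONSTANT = 0.67  # FDG -> glucose lumped constant


@dataclass
class PlasmaPanel:
    """Circulating substrate levels for one animal and session."""

    glucose_mmol_per_L: float
    insulin_uU_per_mL: float
    nefa_umol_per_L: float
    tg_umol_per_L: float

    def __post_init__(self):
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative, got {v}")


@dataclass
class MetabolicEndpoints:
    """Per-animal endpoint bundle (units as reported: nmol/g/min, mL/g/min)."""

    MFAO: float | None = None
    MFAE: float | None = None
    MFAU: float | None = None
    EF: float | None = None
    MFAOUpR: float | None = None
    MFAEUpR: float | None = None
    MFAUUpR: float | None = None
    MBF: float | None = None
    MGU: float | None = None


def _split(params: PalmitateParams) -> tuple[float, float]:
    """Oxidation and esterification shares of the cytosolic branch point."""
    total = params.k3 + params.k4
    if total == 0.0:
        return 0.0, 0.0
    return params.k4 / total, params.k3 / total


def intrinsic_rates(params: PalmitateParams) -> tuple[float, float, float]:
    """(MFAUUpR, MFAOUpR, MFAEUpR) in mL/g/min — unit-concentration fluxes."""
    ox, est = _split(params)
    return params.k1, params.k1 * ox, params.k1 * est


def extrinsic_rates(
    params: PalmitateParams, plasma_nefa_umol_per_L: float
) -> tuple[float, float, float]:
    """(MFAU, MFAO, MFAE) in nmol/g/min at the animal's plasma NEFA level."""
    if plasma_nefa_umol_per_L < 0:
        raise ValueError("plasma NEFA must be non-negative")
    upr_u, upr_o, upr_e = intrinsic_rates(params)
    nefa_nmol_per_mL = plasma_nefa_umol_per_L  # 1 umol/L == 1 nmol/mL
    return (
        upr_u * nefa_nmol_per_mL,
        upr_o * nefa_nmol_per_mL,
        upr_e * nefa_nmol_per_mL,
    )


def extraction_fraction(k1_palmitate: float, mbf: float) -> float:
    """EF = k1/MBF: fatty-acid uptake flux normalised to blood flow."""
    if mbf <= 0:
        raise ValueError(f"MBF must be positive, got {mbf}")
    if k1_palmitate < 0:
        raise ValueError("k1 must be non-negative")
    return k1_palmitate / mbf


def mbf_from_acetate(
    fit: OneTissueParams, extraction: float = DEFAULT_ACETATE_EXTRACTION
) -> float:
    """MBF = K1/E with fixed first-pass acetate extraction E."""
    if not 0 < extraction <= 1:
        raise ValueError(f"extraction must lie in (0, 1], got {extraction}")
    return fit.K1 / extraction


def mgu(
    Ki: float,
    plasma_glucose_mmol_per_L: float,
    lumped_constant: float = DEFAULT_LUMPED_CONSTANT,
) -> float:
    """MGU = Ki*[glucose]/LC in nmol/g/min (glucose mmol/L == nmol/mL)."""
    if lumped_constant <= 0:
        raise ValueError(f"lumped constant must be positive, got {lumped_constant}")
    if Ki < 0 or plasma_glucose_mmol_per_L < 0:
        raise ValueError("Ki and glucose must be non-negative")
    glucose_nmol_per_mL = plasma_glucose_mmol_per_L * 1000.0  # mmol/L -> umol/L
    return Ki * glucose_nmol_per_mL / lumped_constant


def endpoints_from_fits(
    palmitate: PalmitateParams | None = None,
    acetate: OneTissueParams | None = None,
    Ki: float | None = None,
    plasma: PlasmaPanel | None = None,
    acetate_extraction: float = DEFAULT_ACETATE_EXTRACTION,
    lumped_constant: float = DEFAULT_LUMPED_CONSTANT,
) -> MetabolicEndpoints:
    """Assemble the per-animal endpoint bundle from whatever fits are available."""
    out = MetabolicEndpoints()
    if palmitate is not None:
        upr_u, upr_o, upr_e = intrinsic_rates(palmitate)
        out.MFAUUpR, out.MFAOUpR, out.MFAEUpR = upr_u, upr_o, upr_e
        if plasma is not None:
            out.MFAU, out.MFAO, out.MFAE = extrinsic_rates(
                palmitate, plasma.nefa_umol_per_L
            )
    if acetate is not None:
        out.MBF = mbf_from_acetate(acetate, acetate_extraction)
        if palmitate is not None and out.MBF > 0:
            out.EF = extraction_fraction(palmitate.k1, out.MBF)
    if Ki is not None and plasma is not None:
        out.MGU = mgu(Ki, plasma.glucose_mmol_per_L, lumped_constant)
    return out
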