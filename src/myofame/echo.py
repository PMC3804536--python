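"""Echocardiographic structural and functional indices.

Raw M-mode and Doppler measurements become the reported indices as follows:
dimensional measurements (wall thicknesses and internal diameters, mm) are
indexed to body weight in kg; LV mass (mg) is indexed to weight in g;
fractional shortening FS = 100*(LVIDd - LVIDs)/LVIDd; the Tei myocardial
performance index is (IVCT + IVRT)/ET; and the diastolic ratios E/A and E/E'
are computed per animal.  Group summaries average per-animal indices first
(so the mean E/A is a mean of ratios, not a ratio of means); the
ratio-of-means variant is carried alongside as an explicit cross-check
column rather than silently mixed in.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# raw per-animal measurement columns expected from the Vevo-style export
RAW_COLUMNS = [
    "animal", "group", "body_weight_kg",
    "LVPWd_mm", "LVPWs_mm", "LVIDd_mm", "LVIDs_mm", "IVSd_mm", "IVSs_mm",
    "lv_mass_mg", "E_mm_s", "A_mm_s", "Eprime_mm_s", "Aprime_mm_s",
    "IVCT_ms", "IVRT_ms", "ET_ms", "heart_rate_bpm",
]


def index_to_bw(dimension_mm, body_weight_kg):
    """Dimensional measurement indexed to body weight (mm/kg)."""
    bw = np.asarray(body_weight_kg, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    return np.asarray(dimension_mm, dtype=float) / bw


def lv_mass_index(lv_mass_mg, body_weight_g):
    """LV mass index in mg per g of body weight."""
    bw = np.asarray(body_weight_g, dtype=float)
    if np.any(bw <= 0):
        raise ValueError("body weight must be positive")
    return np.asarray(lv_mass_mg, dtype=float) / bw


def fractional_shortening(lvidd_mm, lvids_mm):
    """FS (%) = 100*(LVIDd - LVIDs)/LVIDd."""
    d = np.asarray(lvidd_mm, dtype=float)
    if np.any(d <= 0):
        raise ValueError("LVIDd must be positive")
    return 100.0 * (d - np.asarray(lvids_mm, dtype=float)) / d


def tei_index(ivct_ms, ivrt_ms, et_ms):
    """Tei LV performance index: (IVCT + IVRT)/ET, dimensionless."""
    et = np.asarray(et_ms, dtype=float)
    if np.any(et <= 0):
        raise ValueError("ejection time must be positive")
    return (np.asarray(ivct_ms, dtype=float) + np.asarray(ivrt_ms, dtype=float)) / et


def diastolic_ratios(E, A, Eprime):
    """(E/A, E/E') computed elementwise per animal."""
    A = np.asarray(A, dtype=float)
    Eprime = np.asarray(Eprime, dtype=float)
    if np.any(A <= 0) or np.any(Eprime <= 0):
        raise ValueError("denominator velocities must be positive")
    E = np.asarray(E, dtype=float)
    return E / A, E / Eprime


def derive_indices(records: pd.DataFrame) -> pd.DataFrame:
    """Per-animal index table from raw echo measurements.

    Output rows mirror the standard report: indexed dimensions (mm/kg), LVMI
    (mg/g), FS (%), raw velocities, diastolic ratios, time intervals and Tei.
    """
    missing = [c for c in RAW_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"echo table is missing columns: {missing}")
    r = records
    ea, eep = diastolic_ratios(r["E_mm_s"], r["A_mm_s"], r["Eprime_mm_s"])
    out = pd.DataFrame(
        {
            "animal": r["animal"],
            "group": r["group"],
            "LVPWId (mm/kg)": index_to_bw(r["LVPWd_mm"], r["body_weight_kg"]),
            "LVPWIs (mm/kg)": index_to_bw(r["LVPWs_mm"], r["body_weight_kg"]),
            "LVIDId (mm/kg)": index_to_bw(r["LVIDd_mm"], r["body_weight_kg"]),
            "LVIDIs (mm/kg)": index_to_bw(r["LVIDs_mm"], r["body_weight_kg"]),
            "LVMI (mg/g)": lv_mass_index(r["lv_mass_mg"], r["body_weight_kg"] * 1000.0),
            "IVSId (mm/kg)": index_to_bw(r["IVSd_mm"], r["body_weight_kg"]),
            "IVSIs (mm/kg)": index_to_bw(r["IVSs_mm"], r["body_weight_kg"]),
            "FS (%)": fractional_shortening(r["LVIDd_mm"], r["LVIDs_mm"]),
            "E (mm/s)": r["E_mm_s"].astype(float),
            "A (mm/s)": r["A_mm_s"].astype(float),
            "E/A": ea,
            "E' (mm/s)": r["Eprime_mm_s"].astype(float),
            "A' (mm/s)": r["Aprime_mm_s"].astype(float),
            "E/E'": eep,
            "IVCT (ms)": r["IVCT_ms"].astype(float),
            "ET": r["ET_ms"].astype(float),
            "IVRT (ms)": r["IVRT_ms"].astype(float),
            "Tei Index": tei_index(r["IVCT_ms"], r["IVRT_ms"], r["ET_ms"]),
        }
    )
    return out


def ratio_of_means_crosscheck(records: pd.DataFrame) -> pd.DataFrame:
    """Group-level ratios recomputed from group means (the *other* convention).

    Averaging per-animal ratios and dividing mean numerators by mean
    denominators disagree whenever animals vary; both are reported so the
    discrepancy is visible instead of silently mixed.
    """
    rows = []
    for group, sub in records.groupby("group", sort=True):
        rows.append(
            {
                "group": group,
                "E/A (ratio of means)": sub["E_mm_s"].mean() / sub["A_mm_s"].mean(),
                "E/E' (ratio of means)": sub["E_mm_s"].mean() / sub["Eprime_mm_s"].mean(),
                "Tei Index (from mean intervals)": float(
                    tei_index(sub["IVCT_ms"].mean(), sub["IVRT_ms"].mean(), sub["ET_ms"].mean())
                ),
                "FS (%) (from mean diameters)": float(
                    fractional_shortening(sub["LVIDd_mm"].mean(), sub["LVIDs_mm"].mean())
                ),
            }
        )
    return pd.DataFrame(rows)
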