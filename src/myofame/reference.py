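"""Published group-level scales used as generator defaults and worked inputs.

Means and SDs of the descriptive, hemodynamic and echocardiographic
variables in non-obese type-2-diabetic Goto-Kakizaki (GK) rats and their
Wistar controls (n = 4/group, 24 weeks).  The synthetic cohort generator
draws animals at these scales so that every downstream computation runs in a
realistic regime; they are also the stated inputs of the worked index
calculations (Tei index, percent lipid elevation).
"""

GROUPS = ("Wistar", "GK")

# variable -> group -> (mean, sd)
DESCRIPTIVE = {
    "weight_g": {"Wistar": (491.67, 9.25), "GK": (334.17, 17.78)},
    "insulin_uU_per_mL": {"Wistar": (14.5, 9.98), "GK": (12.32, 3.47)},
    "glucose_mmol_per_L": {"Wistar": (7.80, 0.74), "GK": (9.86, 0.94)},
    "heart_rate_bpm": {"Wistar": (370.33, 31.20), "GK": (323.00, 47.69)},
    "mbf_mL_per_g_min": {"Wistar": (4.32, 0.80), "GK": (2.46, 0.33)},
    "cardiac_nefa_umol_per_g": {"Wistar": (0.76, 0.08), "GK": (1.34, 0.44)},
    "cardiac_tg_ug_per_mg": {"Wistar": (1.74, 0.60), "GK": (2.74, 1.23)},
    "plasma_nefa_umol_per_L": {"Wistar": (1084.5, 270.10), "GK": (1434.25, 215.88)},
    "plasma_tg_umol_per_L": {"Wistar": (877.01, 269.67), "GK": (1219.97, 206.75)},
}

# echocardiographic indices and raw Doppler measures, variable -> group -> (mean, sd)
ECHO = {
    "LVPWId_mm_per_kg": {"Wistar": (3.69, 0.56), "GK": (4.94, 1.00)},
    "LVPWIs_mm_per_kg": {"Wistar": (5.96, 0.72), "GK": (7.35, 1.29)},
    "LVIDId_mm_per_kg": {"Wistar": (15.32, 2.03), "GK": (21.91, 2.11)},
    "LVIDIs_mm_per_kg": {"Wistar": (8.68, 1.44), "GK": (13.60, 2.70)},
    "LVMI_mg_per_g": {"Wistar": (2.45, 0.31), "GK": (2.84, 0.36)},
    "IVSId_mm_per_kg": {"Wistar": (4.03, 0.62), "GK": (4.80, 0.93)},
    "IVSIs_mm_per_kg": {"Wistar": (6.58, 0.96), "GK": (7.66, 1.26)},
    "E_mm_s": {"Wistar": (1041.33, 164.08), "GK": (818.50, 78.10)},
    "A_mm_s": {"Wistar": (813.67, 153.30), "GK": (560.50, 77.88)},
    "Eprime_mm_s": {"Wistar": (54.43, 16.20), "GK": (36.26, 13.54)},
    "Aprime_mm_s": {"Wistar": (51.35, 12.80), "GK": (52.27, 11.95)},
    "IVCT_ms": {"Wistar": (10.98, 0.98), "GK": (12.26, 1.25)},
    "ET_ms": {"Wistar": (61.51, 4.42), "GK": (65.54, 6.23)},
    "IVRT_ms": {"Wistar": (19.09, 3.10), "GK": (24.88, 4.34)},
}


def group_mean(table: dict, variable: str, group: str) -> float:
    return table[variable][group][0]


def group_sd(table: dict, variable: str, group: str) -> float:
    return table[variable][group][1]
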