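"""End-to-end study orchestration: inputs -> fits -> endpoints -> report.

``write_inputs`` lays a synthetic cohort out on disk in the plain-text
formats the pipeline consumes (TAC and blood-sample CSVs, plasma panel,
qPCR Ct tables, echo measurements, truth JSON).  ``run_study`` then works
only from those files: it rebuilds each animal's input function with the
hybrid calibration + metabolite correction, fits the kinetic models,
converts rate constants to metabolic endpoints, analyses the qPCR arrays
and the echo table, and writes group summaries.  Per-animal failures are
collected rather than fatal; the run fails only if no animal succeeds.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import echo as echo_mod
from . import qpcr as qpcr_mod
from . import stats as stats_mod
from .config import RunConfig
from .curves import TimeActivityCurve
from .fitting import fit_one_tissue, fit_palmitate
from .input_function import BloodSampleSet, calibrate_idif, fit_parent_fraction, metabolite_correct
from .kinetics import patlak_slope, spillover_correct
from .rates import PlasmaPanel, endpoints_from_fits
from .simulate import (
    CohortSpec,
    diabetes_array_effects,
    fa_array_effects,
    make_acetate_study,
    make_echo_cohort,
    make_fdg_study,
    make_palmitate_study,
    make_qpcr_table,
)

TRACER_LOADERS = {
    "palmitate": make_palmitate_study,
    "acetate": make_acetate_study,
    "fdg": make_fdg_study,
}


def write_inputs(config: RunConfig, inputs_dir: Path) -> None:
    """Generate a synthetic cohort and write every pipeline input file."""
    inputs_dir = Path(inputs_dir)
    (inputs_dir / "tacs").mkdir(parents=True, exist_ok=True)
    (inputs_dir / "samples").mkdir(exist_ok=True)
    spec = CohortSpec(
        n_per_group=config.n_per_group, seed=config.seed, noise_sigma=config.noise_sigma
    )
    truth: dict = {}
    plasma_rows = []
    for tracer in config.tracers:
        for study in TRACER_LOADERS[tracer](spec):
            stem = f"{study.animal}_{tracer}"
            study.tissue_tac.to_csv(inputs_dir / "tacs" / f"{stem}_tissue.csv")
            study.blood_image_tac.to_csv(inputs_dir / "tacs" / f"{stem}_blood_image.csv")
            study.blood_samples.to_csv(inputs_dir / "samples" / f"{stem}_samples.csv")
            truth.setdefault(study.animal, {})[tracer] = {
                "params": dataclasses.asdict(study.truth_params),
                "mbf": study.truth_extras.get("mbf"),
            }
            if tracer == "palmitate":
                plasma_rows.append(
                    {"animal": study.animal, "group": study.group,
                     **dataclasses.asdict(study.plasma)}
                )
    pd.DataFrame(plasma_rows).to_csv(inputs_dir / "plasma.csv", index=False)
    make_qpcr_table(effects=diabetes_array_effects(), seed=config.seed).to_csv(
        inputs_dir / "qpcr_diabetes.csv", index=False
    )
    make_qpcr_table(effects=fa_array_effects(), seed=config.seed + 1).to_csv(
        inputs_dir / "qpcr_fa_metabolism.csv", index=False
    )
    make_echo_cohort(n_per_group=config.n_per_group, seed=config.seed).to_csv(
        inputs_dir / "echo.csv", index=False
    )
    (inputs_dir / "truth.json").write_text(json.dumps(truth, indent=1))


def _load_tac(path: Path) -> TimeActivityCurve:
    if not path.exists():
        raise FileNotFoundError(f"missing TAC file: {path}")
    return TimeActivityCurve.from_csv(path)


def _prepare_input(image_tac, samples, metabolite_corrected: bool):
    """Hybrid calibration plus (for 11C tracers) metabolite correction."""
    calibrated, factor = calibrate_idif(image_tac, samples)
    whole_blood = TimeActivityCurve(
        image_tac.frames, image_tac.values * factor, units="kBq/mL"
    )
    if metabolite_corrected:
        model = fit_parent_fraction(samples)
        plasma_input = metabolite_correct(calibrated, model)
    else:
        model = None
        plasma_input = calibrated
    return plasma_input, whole_blood, factor, model


def _analyze_animal(config, inputs_dir, animal, group, plasma: PlasmaPanel) -> dict:
    row = {"animal": animal, "group": group}
    palmitate_fit = acetate_fit = None
    ki = None
    for t_idx, tracer in enumerate(config.tracers):
        stem = f"{animal}_{tracer}"
        tissue = _load_tac(inputs_dir / "tacs" / f"{stem}_tissue.csv")
        image = _load_tac(inputs_dir / "tacs" / f"{stem}_blood_image.csv")
        samples = BloodSampleSet.from_csv(inputs_dir / "samples" / f"{stem}_samples.csv")
        plasma_input, whole_blood, factor, _ = _prepare_input(
            image, samples, metabolite_corrected=tracer != "fdg"
        )
        row[f"{tracer}_calibration_factor"] = factor
        if tracer == "palmitate":
            fit = fit_palmitate(tissue, plasma_input, whole_blood, config.fit_config(t_idx))
            palmitate_fit = fit.estimates
            row.update({f"palmitate_{k}": v for k, v in fit.as_dict()["estimates"].items()})
            row["palmitate_converged"] = fit.converged
        elif tracer == "acetate":
            fit = fit_one_tissue(tissue, plasma_input, whole_blood, config.fit_config(t_idx))
            acetate_fit = fit.estimates
            row["acetate_K1"] = fit.estimates.K1
            row["acetate_converged"] = fit.converged
        else:
            corrected = spillover_correct(
                tissue, whole_blood.values, config.fdg_blood_volume_fraction
            )
            patlak = patlak_slope(corrected, plasma_input, t_star=config.patlak_t_star)
            ki = patlak.slope
            row["fdg_Ki"] = ki
    endpoints = endpoints_from_fits(
        palmitate=palmitate_fit,
        acetate=acetate_fit,
        Ki=ki,
        plasma=plasma,
        acetate_extraction=config.acetate_extraction,
        lumped_constant=config.lumped_constant,
    )
    row.update({k: v for k, v in dataclasses.asdict(endpoints).items() if v is not None})
    return row


def run_study(config: RunConfig) -> dict:
    """Execute the full pipeline; returns a bundle of result tables."""
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    inputs_dir = config.resolved_inputs_dir()
    if not inputs_dir.exists():
        if not config.simulate:
            raise FileNotFoundError(f"inputs directory not found: {inputs_dir}")
        write_inputs(config, inputs_dir)
    config.to_yaml(out_dir / "run_config.yaml")

    plasma_df = pd.read_csv(inputs_dir / "plasma.csv")
    rows, errors = [], {}
    for rec in plasma_df.itertuples(index=False):
        plasma = PlasmaPanel(
            glucose_mmol_per_L=rec.glucose_mmol_per_L,
            insulin_uU_per_mL=rec.insulin_uU_per_mL,
            nefa_umol_per_L=rec.nefa_umol_per_L,
            tg_umol_per_L=rec.tg_umol_per_L,
        )
        try:
            rows.append(_analyze_animal(config, inputs_dir, rec.animal, rec.group, plasma))
        except Exception as exc:  # collected per animal, fatal only if universal
            errors[rec.animal] = f"{type(exc).__name__}: {exc}"
    if not rows:
        raise RuntimeError(f"no animal could be analyzed: {errors}")
    endpoints = pd.DataFrame(rows)
    endpoints.to_csv(out_dir / "endpoints.csv", index=False)

    numeric = endpoints.drop(
        columns=[c for c in endpoints.columns if c.endswith("_converged") or c == "animal"]
    )
    try:
        summary = stats_mod.summary_table(numeric, group_col="group")
        summary.to_csv(out_dir / "endpoints_summary.csv", index=False)
    except ValueError:
        summary = None  # a group fell below n=2 after per-animal failures

    qpcr_results = {}
    for label, fname in (
        ("diabetes", "qpcr_diabetes.csv"),
        ("fa_metabolism", "qpcr_fa_metabolism.csv"),
    ):
        path = inputs_dir / fname
        if not path.exists():
            continue
        table = pd.read_csv(path)
        de = qpcr_mod.differential_expression(table)
        de.to_csv(out_dir / f"qpcr_{label}_results.csv", index=False)
        counts = qpcr_mod.count_significant(de, alpha=config.alpha)
        expr = qpcr_mod.expression_matrix(table)
        sig_genes = de.loc[de["p_value"] < config.alpha, "gene"]
        clust = qpcr_mod.cluster_genes(expr.loc[sig_genes])
        (out_dir / f"qpcr_{label}_dendrogram.nwk").write_text(clust.to_newick())
        qpcr_mod.plot_heatmap(expr.loc[sig_genes], clust, out_dir / f"qpcr_{label}_heatmap.png")
        qpcr_results[label] = {"counts": counts, "results": de}

    echo_df = pd.read_csv(inputs_dir / "echo.csv")
    indices = echo_mod.derive_indices(echo_df)
    indices.to_csv(out_dir / "echo_indices.csv", index=False)
    echo_summary = stats_mod.summary_table(indices.drop(columns=["animal"]))
    echo_summary.to_csv(out_dir / "echo_summary.csv", index=False)
    echo_mod.ratio_of_means_crosscheck(echo_df).to_csv(
        out_dir / "echo_ratio_of_means.csv", index=False
    )

    report = ["# Study report", "", "## Metabolic endpoints (mean ± SD)", ""]
    report.append(
        stats_mod.render_markdown(summary)
        if summary is not None
        else "_group summary skipped: fewer than 2 analyzable animals in a group_"
    )
    report += ["", "## Echocardiographic indices", "", stats_mod.render_markdown(echo_summary)]
    for label, res in qpcr_results.items():
        c = res["counts"]
        report += [
            "",
            f"## qPCR {label} array",
            "",
            f"Significant genes at alpha={config.alpha}: {c['total']} "
            f"({c['up']} up, {c['down']} down in GK).",
        ]
    if errors:
        report += ["", "## Per-animal failures", ""]
        report += [f"- {animal}: {msg}" for animal, msg in errors.items()]
    (out_dir / "report.md").write_text("\n".join(report) + "\n")

    return {
        "endpoints": endpoints,
        "summary": summary,
        "echo_indices": indices,
        "echo_summary": echo_summary,
        "qpcr": qpcr_results,
        "errors": errors,
    }
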