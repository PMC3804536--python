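# myofame

Quantitative phenotyping of **myo**cardial **fa**tty-acid **me**tabolism in
the Goto-Kakizaki (GK) rat, a non-obese polygenic model of type-2 diabetes,
against Wistar controls. The package implements the full desk-side analysis
chain of a small-animal PET / echo / qPCR study:

* **Tracer kinetics** — a five-compartment, six-parameter model of
  [¹¹C]palmitate (plasma → extracellular `k1` → cytosolic `k2` → esterified
  `k3` / oxidized `k4` → ¹¹CO₂ washout `k5`, plus a blood-volume fraction
  `f_bv`), a one-tissue [¹¹C]acetate model for myocardial blood flow, and
  Patlak graphical analysis of FDG for glucose utilization.
* **Input functions** — image-derived blood-pool curves calibrated to
  discrete blood samples by a least-squares scale factor and corrected for
  circulating ¹¹C metabolites with a monoexponential-to-plateau parent
  fraction.
* **Estimation** — weighted nonlinear least squares on frame-averaged TACs
  (weights Δt_f / max(C_f, ε), multi-start, seeded), fitting the first
  15 minutes of a 40-frame, 20-minute acquisition.
* **Endpoints** — extrinsic rates MFAU = k1·[NEFA], MFAO = MFAU·k4/(k3+k4),
  MFAE = MFAU·k3/(k3+k4) (nmol/g/min); intrinsic (UpR) capacities at unit
  plasma concentration; extraction fraction EF = k1/MBF;
  MBF = K1_acetate/0.63; MGU = Ki·[glucose]/LC.
* **qPCR arrays** — ΔΔCt analysis of two 84-gene panels normalised to
  Rpl13a/Ldha/Actb, signed fold changes, pooled Student t significance
  tiers, and Spearman-distance complete-linkage clustering for heat-maps.
* **Echocardiography** — body-weight-indexed dimensions, fractional
  shortening, E/A and E/E′, and the Tei index (IVCT+IVRT)/ET.
* **Synthetic data** — a seeded generator producing every input the pipeline
  consumes, with GK/Wistar truth regimes encoding the diabetic phenotype
  (two-fold extrinsic MFAO, MBF ratio 2.46/4.32), so the whole chain is
  exercisable and testable without any animal data.

## Worked example

```python
from myofame.config import RunConfig
from myofame.pipeline import run_study

bundle = run_study(RunConfig(output_dir="results/study", seed=42))
print(bundle["endpoints"].groupby("group")[["MFAO", "MBF", "EF", "MGU"]].mean().round(2))
```

simulates a 4 + 4 cohort, fits every animal and prints

```
          MFAO   MBF    EF     MGU
group
GK      724.14  2.59  0.31  392.64
Wistar  414.59  4.33  0.17  542.13
```

— the GK group shows a 1.75-fold higher fatty-acid oxidation rate
(truth ratio 2.0 at the regime level) despite a 40 % lower blood flow,
hence a near-doubled extraction fraction, and reduced glucose utilization.
The same run writes `endpoints.csv`, group summary tables with significance
marks, qPCR results with dendrograms and heat-maps, and the echo index
table under `results/study/`.

The numbered drivers under `analysis/` tell the story step by step:

```bash
python analysis/01_simulate_cohort.py   # inputs at the published scales
python analysis/02_fit_kinetics.py      # fits vs generating truth
python analysis/03_metabolic_endpoints.py
python analysis/04_qpcr_expression.py
python analysis/05_echo_function.py
```

A `myofame` console script exposes the same steps as subcommands
(`simulate`, `fit-palmitate`, `fit-acetate`, `fit-fdg`, `qpcr`, `echo`,
`report`, `run-study`).

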