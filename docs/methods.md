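# Methods

## Palmitate compartment model

The myocardial handling of [¹¹C]palmitate is described by four tissue pools
driven by the metabolite-corrected plasma concentration Cp(t):

    dC1/dt = k1·Cp − k2·C1          extracellular
    dC2/dt = k2·C1 − (k3+k4)·C2     cytosolic
    dC3/dt = k3·C2                  esterified (trapped on the scan timescale)
    dC4/dt = k4·C2 − k5·C4          oxidized, cleared as ¹¹CO₂

with zero initial conditions. The measured region-of-interest signal is the
frame average of (1−f_bv)·(C1+C2+C3+C4) + f_bv·C_blood — PET frames
integrate activity, so mid-frame sampling is never used. k1 carries
mL/g/min, k2–k5 are 1/min, f_bv is a unitless spillover/blood-volume
fraction in [0,1]. The serial/branched topology (no back-diffusion edge)
allocates all five rate constants to forward transport, the
esterification/oxidation branch, and CO₂ washout. The acetate flow model is
the one-tissue reduction (K1, k2, f_bv); FDG uses the irreversible
two-tissue model whose net-uptake constant is Ki = K1·k3/(k2+k3).

### Solvers

Inputs are piecewise linear by contract (zero before the first sample), so
the linear system has an exact solution. The default path writes every
compartment as a partial-fraction combination of exponential convolutions
E_λ(t) = ∫Cp(s)e^{−λ(t−s)}ds, each computed by an exact per-segment
recursion (O(n), stable via `expm1` and a short series for λh < 1e−4). When
two of the eigenvalues {k2, k3+k4, k5} lie within 1e−6 min⁻¹ of each other
the partial-fraction weights lose precision, and the solver switches to an
augmented matrix-exponential propagator that is exact for piecewise-linear
forcing regardless of spectrum. Both paths are cross-checked against each
other and against a tight-tolerance ODE integration in the tests.

### Identifiability and the ordering convention

The total-tissue curve is *exactly* invariant under permutations of the
three eigenvalues (k2, k3+k4, k5) with compensating adjustments of the
k3/k4 branch: all pole assignments reproduce the measured TAC to machine
precision with non-negative rates. The identifiable quantities are k1,
f_bv, the oxidation fraction k4/(k3+k4), and the eigenvalue *set* — which
is exactly what the physiological endpoints (MFAU, MFAO, MFAE, EF and their
intrinsic counterparts) depend on. As is standard for models with
exchangeable components, the estimator works in an order-constrained chart
k2 ≤ k3+k4 ≤ k5 (parameterised as k2, two non-negative gaps, and the branch
fraction φ = k4/(k3+k4)), which selects one canonical representative per
equivalence class and removes the spurious multiple global minima. Reported
rate constants are to be read under that convention; the synthetic truth
regimes are stated in the same chart.

## Estimation

Weighted NLLS with w_f = Δt_f / max(C_f, ε), ε defaulting to 1 % of the
TAC maximum — the usual count-statistics weighting for frame-averaged PET.
Only frames fully inside the fit window (default [0, 15] min of the
20-minute scan) and inside the input-function support enter the objective.
The optimiser is a bounded trust-region least-squares routine with default
bounds k1 ∈ [0, 20] mL/g/min, rates ∈ [0, 10] min⁻¹, fractions ∈ [0, 1];
five seeded starts (log-uniform perturbations within ×3, fractions redrawn
uniformly) guard against local minima, and identical seeds give
bit-identical results. Approximate standard errors come from the
Gauss–Newton covariance at the optimum and are reported, not used for
inference. Monte-Carlo exercises in the test suite use two starts and
tolerances of 1e−9, which match the five-start deep-tolerance results on
this problem at a fraction of the cost.

Patlak analysis regresses Ct/Cp on ∫Cp/Cp over frames with mid-time
≥ t* = 7.5 min. On a spillover-mixed myocardial TAC the Patlak slope
estimates (1−f_bv)·Ki — the blood term only shifts the intercept — so the
pipeline first removes an assumed vascular fraction (default 0.3, matching
the generator's regime; on real data this constant is the main source of
MGU scale uncertainty). The remaining t*-dependent equilibration bias is
about −5 % for the slow FDG kinetics simulated here.

## Input functions

The image-derived blood-pool curve is calibrated by the single
least-squares ratio Σ(img·sample)/Σ(img²) at the discrete sample times
(≥ 2 samples past 5 min required); 5–6 samples cannot constrain a richer
time-varying warp. The parent fraction follows
f(t) = (1−a)·e^{−bt} + a with a ∈ [0,1], b ≥ 0 fitted per tracer from the
measured fractions; palmitate and acetate carry independent models and FDG
none (metabolite-stable). The correction is a pointwise product and never
increases activity.

## Endpoint conversions

Plasma concentrations convert as 1 μmol/L = 1 nmol/mL, so k1 (mL/g/min) ×
NEFA (nmol/mL) is nmol/g/min directly. MBF uses a fixed first-pass acetate
extraction of 0.63 (configurable); MGU uses a lumped constant of 0.67
(configurable). Both constants are conventions of the respective tracer
literatures rather than fitted quantities; every endpoint scales inversely
with them, which matters when comparing absolute values across studies.

## qPCR analysis

ΔCt normalises each well to the mean of Rpl13a, Ldha and Actb in the same
replicate; undetermined wells are imputed at the 40-cycle ceiling and
flagged. Fold change is 2^−ΔΔCt with the vendor's signed convention
(−1/FC for down-regulation, so |FC| ≥ 1 always). Significance is the
classic equal-variance two-sample Student t on per-replicate ΔCt values,
tiered at 0.05/0.01/0.001; no multiple-testing correction is applied by
default (a Benjamini–Hochberg column is available) because the reported
counts are nominal-α counts. With 84 genes per array, a nominal α = 0.05
test necessarily admits ≈ 0.05 × (number of null genes) false positives,
so a count of significant genes slightly exceeding the number of true
effects is expected behaviour, not a defect.

Clustering uses d = 1 − Spearman ρ across per-replicate −ΔCt values and
complete linkage, implemented in-package so that merge ties break
deterministically toward the lexicographically smallest cluster labels
(library linkage routines do not expose a tie rule). Constant rows have
undefined ρ and receive unit distance with a warning. On matrices with
distinct distances the result coincides with standard complete linkage,
which the tests verify against both a brute-force oracle and the scipy
implementation.

## Echo indices

Dimensional measurements are indexed to body weight (mm/kg; LV mass in
mg/g), FS = 100·(LVIDd−LVIDs)/LVIDd, Tei = (IVCT+IVRT)/ET, and E/A, E/E′
are computed per animal. Group summaries average per-animal indices; the
ratio-of-means alternative is emitted as an explicit cross-check table
because the two conventions genuinely disagree under inter-animal
variability and silently mixing them is a classic reporting error.

## Synthetic cohort

The generator emulates a 4 + 4 study at the published group scales. Truth
regimes: Wistar palmitate (k1 = 0.7, k2 = 0.35, k3 = k4 = 0.185,
k5 = 0.4, f_bv = 0.3), GK with oxidation fraction 0.638 and k1 solved from
the constraint that extrinsic MFAO at the group-mean NEFA levels is exactly
twice the Wistar value (so the esterification rate rises only marginally);
MBF 4.32 vs 2.46 mL/g/min, acetate K1 = MBF × 0.63; FDG Ki 0.05 vs 0.03
mL/g/min. Per-animal kinetic parameters get 5 % lognormal jitter and
plasma/echo variables are drawn at the published means and SDs, so cohort
ratios fluctuate around the regime truth exactly as a real n = 4 study
would. Blood curves are gamma-variate boluses (peak within the first
minute) with a slow recirculation tail, sampled at 0.05-min resolution over
20 minutes on the default 24×5 s / 8×15 s / 8×120 s frame schedule. TAC
noise is Gaussian with variance σ²·C_f/Δt_f (σ = 0.05 by default), the
standard approximation for reconstructed PET; the image-derived blood curve
is deliberately mis-scaled by 1/1.15 so the hybrid calibration step is
genuinely exercised, and blood samples and parent fractions carry 3 % and
0.02 absolute noise respectively.

What the generator does **not** emulate: partial-volume geometry beyond the
scalar f_bv, dispersion/delay of the arterial curve, radioactive decay (all
inputs are decay-corrected by construction), plasma-to-whole-blood
partitioning, correlated biological covariation between NEFA levels and
kinetic parameters, and probe-efficiency differences between qPCR genes.
Passing tests therefore demonstrate correctness of the estimators under the
stated noise model, not robustness to those real-data effects.

qPCR tables place housekeeping Cts at Normal(16, 0.2) and targets at the
replicate housekeeping mean plus a Uniform(2, 10) basal offset plus the
group effect plus Normal(0, 0.25) replicate noise; the shipped effect maps
contain 17 (diabetes) and 41 (fatty-acid metabolism) effects of at least
6 replicate-SDs, including a +3.46-cycle (>11-fold down) resistin-like
effect, mirroring the published hit census as a construction rather than a
reproduction.

## Problem sizes and numerical defaults

Default test-suite workloads: 100-draw solver-oracle comparison, 100-seed
Monte-Carlo recovery at σ = 0.05, one full 4 + 4 cohort fit, 40-seed qPCR
count study. Solver grids refine each frame with 4 interior points and the
degeneracy threshold for the partial-fraction path is 1e−6 min⁻¹.
Tie-breaks: clustering merges prefer lexicographically smaller labels;
multi-start fits keep the lowest weighted RSS and report the winning start
index.

## Known limitations

* Individual rate-constant labels beyond the identifiable invariants rest
  on the ordering convention; comparisons of k2/k5 across studies using a
  different convention are not meaningful.
* The extrinsic/intrinsic rate formulas follow the adopted no-back-flux
  topology; a topology with a C1→plasma edge would change the k1
  interpretation.
* MGU and MBF are only defined up to the assumed lumped constant and
  acetate extraction fraction.
* The Patlak vascular-fraction correction uses a fixed assumed f_bv rather
  than a per-animal estimate.
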