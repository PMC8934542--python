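# Methods

This note documents the models and procedures implemented in `spectriage`,
the defaults chosen where the underlying assay leaves the design open, and
what the synthetic validation does and does not demonstrate.

## Synthetic cohort generator

Real spectra for this assay are proprietary, so every pipeline stage is
exercised on synthetic cohorts that reproduce the *structure* of the study
data rather than its biochemistry.

**Generative model.** Each spectrum on a shared descending wavenumber grid
(default 4000→450 cm⁻¹ at 1 cm⁻¹ spacing — the range is not fixed by the
assay description, so the standard mid-IR transmission window is used) is

    A(ν) = s · Σ_b a_b·m_p·m_w · exp(−(ν−c_b)²/2σ_b²) + P(ν) + ε(ν)

with Gaussian bands `b`, patient- and well-level multiplicative amplitude
factors `m_p ~ N(1, patient_sd)`, `m_w ~ N(1, well_sd)` (truncated positive),
a global scatter factor `s ~ N(1, scatter_sd)`, a degree-≤2 polynomial
baseline `P` with coefficients `~ N(0, baseline_coeffs_sd)`, and white noise
`ε ~ N(0, replicate_sd)` per point. Disease adds
`Δ ~ N(amplitude_shift, per_patient_sd)` to one band's amplitude, constant
across a patient's nine replicates — the simplest hierarchy under which
replicate-consensus voting is meaningful.

**Band positions** default to canonical dried-serum features (amide A ~3300,
amide I ~1650, amide II ~1550, COO⁻ ~1400, amide III/PO₂⁻ ~1240,
carbohydrate ~1080 cm⁻¹). They are neutral placeholders: the true
discriminatory regions of the real assay are not public, and no equivalence
is claimed.

**Noise defaults** (chosen once as a realistic serum-FTIR regime):
patient 5% and well 2% multiplicative amplitude SD, replicate white noise
2×10⁻³ AU, baseline coefficient SDs (0.01, 0.005, 0.002) AU, scatter 3%. The
default disease effect (+0.05 AU on amide I, patient SD 0.02 AU) gives
patient-level separation in the AUC ≈ 0.8 range after preprocessing —
deliberately imperfect, like a real triage assay.

**Cohort composition.** Positives are exactly `round(n·prevalence)`;
subtypes are apportioned among positives by largest remainder, so the
603-patient / 7.8% default reproduces the 47-tumor composition
(20/12/10/2/2/1) exactly. Per-patient random streams are split off the
master seed by counter (`SeedSequence(seed, spawn_key=(i,))`), so cohort
content is order-invariant and bit-reproducible.

**Validation configurations.** `strong_effect_config` raises the shift to
0.12 AU (patient SD 0.01) and injects it on the *isolated* carbohydrate band
at 1080 cm⁻¹. The isolation matters for the parameter-recovery check: under
vector normalization, a shift on a band overlapping another (amide I next to
amide II) expresses most strongly in the overlap region between them, so
"peak importance in the bin containing the injected center" would be
unidentifiable by construction. `null_effect_config` zeroes the effect for
negative-control runs.

**What the simulator does not emulate:** instrument physics (interferograms,
apodization, atmospheric lines), drying-film spatial heterogeneity,
biological covariance between bands, co-morbidity structure (e.g. stroke
patients), and batch/instrument drift. Passing tests therefore demonstrate
the *pipeline's* correctness and statistical behavior under a known
generative model — not clinical performance on real serum.

## Preprocessing

Fixed order: cut → baseline-correct → normalize. Defaults: fingerprint
region 1800–1000 cm⁻¹ (801 features at 1 cm⁻¹), rubberband baseline (lower
convex hull by monotone chain, subtracted after linear interpolation between
hull supports), Euclidean vector normalization. The real assay's
preprocessing is undisclosed; these are standard serum-FTIR choices, made
explicit and configurable (`none`/`polynomial(0–2)`/`rubberband`;
`none`/`vector`/`min-max`). The polynomial option is an iterative restricted
fit (clip-to-fit, ≤40 iterations), which recovers band amplitudes over a
smooth baseline to well under 1%.

QC: a spectrum whose corrected peak-to-peak amplitude falls below
`qc_min_signal` (default 10⁻⁶ AU) is flagged, excluded from training, and
reported — never silently dropped. A patient's flagged replicates reduce the
consensus denominator (see below); more than 50% failures aborts the run as
a configuration error.

Rubberband correction pins the first and last points of the cut to exactly
zero, so those features have zero variance across any cohort; the classifier
drops them with a warning and assigns them zero coefficient.

## PLS-DA classifier

PLS1 regression of the 0/1 class indicator on centered features, by NIPALS
with deflation: per component `w = Xᵀy/‖Xᵀy‖` (iterated to tolerance 10⁻¹⁰,
≤500 iterations, though the univariate update converges immediately),
`t = Xw`, `p = Xᵀt/tᵀt`, `q = yᵀt/tᵀt`, then `X ← X − tpᵀ`, `y ← y − qt`.
Sign convention: the largest-magnitude weight element is positive. The
regression coefficients for every component count `k ≤ k_max` are recovered
from one fit (`B_k = W_k(P_kᵀW_k)⁻¹q_k`), which the tuner uses to sweep the
component grid at one NIPALS fit per fold. Agreement with an independent
NIPALS implementation (scikit-learn `PLSRegression`) is verified in the test
suite to 10⁻⁸; scikit-learn is never the implementation.

The latent regression score is calibrated to a probability by univariate
logistic regression (maximum likelihood with a weak ridge, C = 1000, so the
slope stays finite on separable data); probabilities are clipped to
(10⁻¹², 1−10⁻¹²). The classifier is a disclosed, fully specified stand-in —
any calibrated per-spectrum probability model satisfying the same interface
could be plugged in.

## Consensus rule

Patient positive iff ≥ `min_positive` (default 5) of the expected 9
replicate calls are positive (call: probability ≥ threshold). With 9
replicates this is an odd majority, so ties are impossible. For short sets
(QC failures) the default `proportional` policy preserves the 5/9 ≈ 0.556
operating fraction (`positives/available ≥ 5/9`); `strict` keeps the
absolute count. Patients with zero usable spectra are reported
`indeterminate` and excluded from sensitivity/specificity denominators but
counted in reports. The positive-replicate fraction at the operating
threshold is retained as the patient-level continuous score; a
median-probability alternative is selectable.

## Threshold selection and nested cross-validation

`select_threshold` sweeps a grid (default 0.01 steps over (0.01, 0.99)) of
per-spectrum thresholds and computes patient-level sensitivity/specificity
after consensus. Modes: `sensitivity_tuned` (maximize specificity subject to
sensitivity ≥ floor), `specificity_tuned` (symmetric), `youden`
(maximize sens+spec−1). Ties break toward the larger threshold (the higher
specificity margin); an unattainable constraint returns the
constrained-metric maximizer flagged `feasible=False`. The implementation is
verified against exhaustive search on hundreds of random instances.

`nested_cv` runs 51 outer stratified train/test splits (test fraction 1/3 —
the split fraction is not fixed by the protocol description, so a
conventional holdout third is used). Within each outer-train set, 5-fold
stratified CV produces out-of-fold probabilities per candidate component
count; `(k, t)` is selected by the tuning mode's objective (the constrained
metric itself, not accuracy), with component-count ties toward the smaller
model. Outer-test sensitivity/specificity/AUC are recorded per split. The
final model takes the modal `k` across splits (ties toward fewer
components), re-selects `t` by one more CV pass over the full cohort, and
refits on all spectra. All splitting is at the patient level so a patient's
replicates never straddle a split (asserted structurally); folds that lose a
class are redrawn from successive streams and a repeated failure is an
error. Everything is driven by a single seed; repeat runs are identical.

## Evaluation

ROC curves sweep every distinct patient score plus +∞ (call: score ≥
threshold); AUC is the trapezoid over (1−specificity, sensitivity) after
lexicographic (FPR, TPR) ordering, which equals the Mann–Whitney pair
probability with ties counted ½. PPV/NPV use the Bayes identities at an
arbitrary prevalence (default: observed cohort prevalence; the 1% triage
scenario overrides it). Reported percentages round half-away-from-zero to
one decimal. Detection tables tally identified/actual per tumor subtype plus
a TOTAL row. Permutation importance jointly permutes each wavenumber bin's
columns across spectra (bins must partition the cut range) and reports the
mean drop in patient-level AUC over seeded permutations.

## Triage economics

Expected counts for a screening population: `tp = round(pop·prev·sens)`,
`tn = round(pop·(1−prev)·spec)` (half away from zero), with `fn`/`fp` as
complements so the four counts always partition the population. Savings
modes: `printed_reconciliation` — `tn × (ct + mri)` — is the unique member
of the candidate set `{tn·c, ½(tn+fn)·c, (tn+fn)·c, ½(tn+fn)·2c}` that
reproduces all four published scenario figures (£1,136,025 / £2,272,050 /
$11,248,875 / $22,497,750), as `reconcile_savings_formula()` verifies at run
time; `half_imaging` implements the stated "half of negative-test patients
are still imaged" assumption for prospective analysis. No currency
conversion; scenarios are single-currency. The comparator registry (NICE
CNS-symptom PPV 2.9%, Kernick red-flag 2.8%, headache alone 0.1% PPV and
14.2% sensitivity, 6-month symptom combination 7.2%) supports
fold-improvement reporting.

## Problem sizes and numerical choices

The study-scale validation runs use 603 patients × 9 replicates with the
component grid reduced to {4, 8} (components are nested, so larger grids
cost little extra; {4, 8} brackets the useful range for a single-band
effect). A full 51×5 nested CV on one CPU takes ~1.5 min per cohort.
NIPALS tolerance 10⁻¹⁰; zero-variance guard at variance 10⁻²⁴ (catches
exact zeros and float-accumulation fuzz of constant columns); probability
clipping 10⁻¹²; absorbances serialized at 6 significant digits (below the
simulated noise floor).

## Known limitations

- The commercial algorithm, its preprocessing and its training data are all
  undisclosed; this package is an independent, fully specified pipeline with
  the same interfaces and decision rules, not a reproduction.
- Patient-level ROC construction from replicate calls is not uniquely
  defined by the study description; the positive-replicate fraction is the
  default here, with a median-probability alternative.
- The synthetic generator's Gaussian-band model cannot validate robustness
  to real-world confounders (hemolysis, medication, co-morbidity spectra).
- No bootstrap confidence intervals are produced (extension point).
- JCAMP-DX import supports single-block AFFN `(X++(Y..Y))` data only.
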