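# Methods

## Scope and design

`bonescatter` implements a two-group chemometric classification workflow for
powder X-ray diffractograms of bone, exercised end to end on synthetic
cohorts. The package is organised around two objects in the statsmodels
style: `PCLDA` (the model, built from a preprocessed cohort matrix) and
`PCLDAResults` (estimates, selection, decision rule, `summary()`), with
`cross_validate` producing a `CVResult`. Simulation, preprocessing and
interpretation are plain functions grouped by stage
(`simulate`, `preprocess`, `interpret`), and a thin `click` CLI
(`bonescatter simulate|preprocess|crossval|interpret|stepstudy|pipeline`)
drives the same library code from a single YAML config with full
run-provenance output.

## The synthetic cohort generator

### What it emulates

Each diffractogram is a noise-free model plus counting noise:

* **Apatite Bragg peaks.** Hexagonal apatite (a = 9.418 Å, c = 6.8837 Å)
  with reflections 002, 210, 211, 300, 202, 310, 222, 213, 004 and
  order-of-magnitude relative amplitudes (211 strongest). Positions follow
  Bragg's law at Cu Kα1 (λ = 1.5406 Å); widths follow the Scherrer relation
  `FWHM = Kλ/(L cos θ)` with K = 0.9 and crystallite size L in nm; profiles
  are pseudo-Voigt with η = 0.3.
* **Silicon internal standard.** Cubic a = 5.43119 Å (111 at 28.44°), spiked
  at `si_fraction` of the apatite scale. The standard's lines are rendered
  as narrow (0.05° FWHM) pure Gaussians: a coarse, well-annealed standard
  shows no size-broadened Lorentzian tails, so its signal is fully contained
  inside the removal windows — which is what makes dopant-level independence
  after removal an exact property rather than an approximation.
* **Amorphous humps.** Gaussians at 20° (FWHM 9°, lipid-like) and 30°
  (FWHM 10°, collagen helical-rise-like), heights in counts.
* **Flat background**, a per-sample constant 2θ displacement offset
  (Normal, σ = `shift_sd` = 0.05°), and Poisson counting noise.

### Group effects (the study conditions)

The fracture/non-fracture contrast follows the physico-chemical mechanism
the workflow is meant to detect: reduced calcium channel-site occupancy
raises the 002/004 structure factors and lowers 310, crystallite size is
reduced in fragile bone, and the groups differ in the lipid hump and the
overall quantity of scatter. Defaults:

| parameter | fracture | non-fracture |
|---|---|---|
| 002, 004 amplitude | ×1.00 | ×1.15 |
| 310 amplitude | ×1.00 | ×0.85 |
| crystallite size | 15 nm | 18 nm |
| 20° hump height | 5000 | 6500 counts |
| 30° hump height | 2400 | 2400 counts |
| overall scale | 1.00 | 1.10 |

No quantitative effect sizes exist to copy, so these were calibrated once —
jointly with the variability parameters below — so that the default
study-scale cohort classifies in the low-90s% under both leave-one-out
schemes and degrades only mildly (≲ 6 points over seeds 1–5) when
re-interpolated at a 2° step, and then frozen.

Two variability layers make the problem statistically honest: every effect
parameter receives a lognormal perturbation per patient (σ = 0.05) and
again per sample (σ = 0.09). The patient layer induces within-patient
correlation, which is what makes leave-one-patient-out genuinely different
from leave-one-sample-out; the sample layer sets the within-group overlap
that fixes the achievable error rate.

Counting statistics are sized for a laboratory diffractometer integrating
~150 s per point: peak counts of order 10⁴ (area scale 40 counts·deg per
relative-amplitude unit, background 800 counts). At that level Poisson
error is small next to the biological variability — which is why coarse
re-interpolation, which decimates channels without averaging noise, costs
little performance, whereas an unrealistically low count scale makes the
step-size study erratic.

The default cohort layout reproduces the emulated study demography exactly:
54 fracture samples over 19 patients (18 male/4 donors aged 74–78, 36
female/15 donors aged 73–90) and 54 non-fracture samples over 54 donors
(27 + 27, ages 66–93 / 60–90). `CohortDesign.balanced(n)` provides small
symmetric cohorts for testing.

### Reproducibility

One master seed; each patient and each sample owns a `default_rng([seed,
index])` substream, so cohorts are bit-reproducible and a sample's draws do
not depend on cohort composition. Poisson counts are drawn by inverse CDF
against one uniform per channel (common random numbers): two configurations
that differ only where their noise-free models differ (e.g. the dopant
level inside Si windows) receive identical counts everywhere else.

### What it does not emulate

No Rietveld-level physics: no preferred orientation, no Kα2 doublet, no
angle-dependent displacement aberration (the shift is a constant 2θ offset,
matching the corrector's model), no incoherent/Compton background, no
detector nonlinearity. Group effects are multiplicative and log-normally
perturbed — real biological covariance structure (e.g. correlated
composition/size changes) is richer. Passing tests therefore demonstrate
that the *pipeline* is correct and leakage-free under realistic geometry
and counting statistics, not that real bone cohorts will classify at these
rates.

## Preprocessing

Per-sample chain, in fixed order: **estimate shift → re-grid → remove Si →
min-max normalize**, then cohort-level **mean-centring**.

* **Shift estimation.** For each silicon reference line inside 10–80°, a
  ±0.35° window is searched; a peak is detected when the window maximum
  reaches 3× the window median (a robust local background level). The
  observed position is the intensity-weighted centroid after subtracting
  the chord between the window's edges; the offset estimate is the mean of
  (centroid − reference) over detected windows. Samples with no detectable
  standard fall back to zero shift with a warning.
* **Re-gridding** linearly interpolates intensities from the
  displacement-corrected axis onto the common 10–80°/0.013° grid (5385
  channels; flat extrapolation at the edges).
* **Si removal** replaces each ±0.35° window with the straight bridge
  between its edge values. Windows are bridged, not imputed from
  neighbours, so no statistic of the spike can survive. Note the Si 220
  window (47.30°) genuinely overlaps the apatite 222 flank (46.71°); the
  bridge removes that shoulder identically in every sample.
* **Normalization** is per-sample min-max over the analysis range, applied
  after Si removal so the spike can never set the maximum. Per-sample
  normalization is fold-independent by construction; only mean-centring is
  a cohort statistic, and it is recomputed inside every CV fold. An
  unnormalized mode is available behind a config switch.
* **Step-size re-interpolation** (the fidelity study) happens after Si
  removal: at 1–2° steps the 0.35° windows are unresolvable, and
  re-interpolating first would alias the sharp standard lines into coarse
  channels with sub-grid-dependent amplitude — nuisance structure a
  spike-free low-fidelity instrument would not contain.
* **Region exclusion** drops channels inside the given 2θ windows (used for
  the 16–24° lipid-hump robustness analysis); dropped, not zeroed, so the
  excluded feature leaves no shape residue.

## Classification

PCA is computed by thin SVD of the centred training matrix, capped at
min(n − 2, 50) components (bounds the ANOVA multiple-testing burden while
retaining essentially all variance; loadings' signs are fixed so each
component's dominant element is positive). Component selection uses
per-component one-way ANOVA at α = 0.05, uncorrected — deliberately: the
emulated workflow applies no multiplicity adjustment, and the permutation
null in the test suite quantifies what that costs. If no component passes,
the single lowest-p component is used (logged) so every fold emits a
prediction.

LDA uses the pooled within-class covariance (divisor n − 2) with a
`1e-8·trace/s` ridge only if the solve fails; the direction is normalized
and oriented so the fracture mean scores negative; the threshold is the
midpoint of the projected group means (equal priors). Exact threshold ties
predict non_fracture. Fracture is the positive class throughout.

Cross-validation is "full recalculation": every fold recomputes centring,
PCA, selection and LDA from its training rows only. Sample mode yields n
folds; patient mode one fold per patient, holding out all of a patient's
samples together. `permutation_null_accuracies` permutes group labels at
the patient level (the exchangeability unit; also the only permutation
consistent with the patient→group invariant) and re-runs the whole CV per
permutation.

## Interpretation

The discriminant profile is `Σ_j w_j ℓ_j` over the selected components —
LD-weight weighting is canonical; a significance variant replacing |w_j|
by (1 − p_j) is available for comparison since both readings of
"weighted by significance" are defensible. Annotation smooths the profile
with a 0.08° Gaussian (well below the ~0.5° peak scale, enough to kill
single-channel noise), finds extrema of either sign with prominence ≥ 15%
of the smoothed maximum, and labels each with the nearest apatite
reflection within 0.3° (≈ half a typical peak FWHM at 20 nm crystallite
size); nearest wins, ties to the lower angle, no match → "unassigned".
A 5% prominence threshold without smoothing marks over a thousand noise
wiggles on a native-resolution profile; the defaults above yield ~13
extrema that coincide with the apatite lines. Both knobs are arguments.

## Numerical choices and edge cases

* Grid arithmetic: a (start, stop, step) grid has
  `floor((stop − start)/step) + 1` channels; 10–80° at 0.013° gives 5385.
  Grids must be uniform to 1e−9°; validation rejects anything else.
* `pseudo_voigt` area-normalizes both components analytically; quadrature
  recovers the nominal area to ~1% on a ±20·FWHM window (Lorentzian tails
  carry the remainder).
* Min-max normalization rejects constant patterns; PCA rejects non-centred
  input (column-mean tolerance 1e−8 relative); CV refuses folds whose
  training set drops below two samples in either group.
* Upsampling in `reinterpolate_step` is refused — interpolation cannot
  create information and a finer grid would only fake it.

## Known limitations

* The constant-offset shift model ignores the cos θ dependence of true
  specimen-displacement error; generator and corrector share the
  convention, so the simplification is internally consistent but transfers
  only approximately to real goniometer data.
* ANOVA selection at uncorrected α = 0.05 admits ≈ 2.5 false components
  per 50 tested; the LDA weights shrink their influence but do not remove
  it.
* Identical performance of sample-wise and patient-wise CV on the default
  cohort is a property of the simulated effect structure, not a general
  fact; cohorts with stronger patient-level effects separate the two modes.
* Min-max normalization ties the scale to the global maximum (the 211
  region); cohorts whose dominant peak itself differs between groups would
  conflate scale with shape, and the area-normalization alternative would
  be preferable.
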