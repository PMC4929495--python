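# bonescatter

Coherent X-ray scatter (powder diffraction) classification of bone into
fracture and non-fracture groups, built as a tested, reusable pipeline:

* a **physics-based synthetic cohort generator** for bone-like
  diffractograms (Bragg peaks of hexagonal apatite, Scherrer size
  broadening, pseudo-Voigt profiles, a silicon internal standard, broad
  lipid/collagen humps, sample-position shifts, counting noise),
* the **preprocessing chain** for Si-spiked powder patterns
  (internal-standard shift estimation, common-grid re-interpolation,
  Si-peak removal, min-max normalization, mean-centring),
* **principal-component-fed linear discriminant analysis (PC-LDA)** with
  one-way ANOVA component selection under leakage-free leave-one-sample-out
  and leave-one-patient-out cross-validation,
* **interpretation tools**: the discriminant loading profile annotated with
  apatite Miller indices, and a step-size degradation study emulating
  lower-fidelity instruments.

The intended users are researchers in diffraction-based tissue
characterisation who need a transparent, fully reproducible reference
implementation of this chemometric workflow — including realistic synthetic
cohorts on which every stage can be validated end to end.

## The model

Each sample is a diffractogram `x ∈ R^p` (intensity vs scattering angle 2θ,
10–80° in 0.013° steps). After per-sample preprocessing, the cohort matrix
is mean-centred, `X̃ = X − 1x̄ᵀ`, and decomposed into principal components
`X̃ = T Lᵀ` (loadings `L` orthonormal, scores `T`). Each score column is
tested against the two group labels with a one-way ANOVA
(`F = MS_between / MS_within` on (1, n−2) degrees of freedom) and components
with `p < 0.05` are retained. On the retained scores, Fisher's linear
discriminant

&nbsp;&nbsp;&nbsp;&nbsp;`w ∝ S_W⁻¹ (μ_fracture − μ_non-fracture)`,

with pooled within-class covariance `S_W` and the equal-prior midpoint
threshold, classifies a held-out sample from its LD score
`s = wᵀ L_selᵀ (x − x̄)`. Cross-validation recomputes *everything* —
centring, PCA, ANOVA selection, LDA — inside every fold; in patient mode no
sample of the test patient touches training. Sensitivity and specificity are
reported with fracture as the positive class. The discriminant loading
profile `Σ_j w_j ℓ_j` folds the classifier back into 2θ space: negative
peaks indicate fracture, positive peaks non-fracture.

## Worked example

```python
import bonescatter as bs

cfg = bs.default_config(seed=1)                 # 54+54 samples, 19+54 patients
cohort, table = bs.simulate_cohort(cfg)
matrix = bs.preprocess_cohort(cohort, table)    # shift-correct, de-spike, normalize

cv = bs.cross_validate(matrix, mode="patient")  # leave one patient out
print(cv.summary())
```

```
Cross-validation (leave_one_patient_out), 73 folds, 108 samples
  confusion (fracture positive): TP=50 FN=4 TN=50 FP=4
  sensitivity: 92.6%
  specificity: 92.6%
```

Of 54 fracture samples, 50 are recognised (sensitivity 92.6%) and of 54
non-fracture samples 50 (specificity 92.6%), with no test patient's samples
ever informing the model that scores them. Fitting once on the whole cohort
exposes the model internals:

```python
results = bs.PCLDA(matrix).fit()
print(results.summary())
```

```
PC-fed LDA (two-group, fracture negative on the LD axis)
  channels:            5385
  components tested:   50
  selected (p<0.05):   [0, 1, 2, 3, 11]
  decision threshold:  -0.0000

  PC   var.expl.   ANOVA F      p        LD weight
    0     77.23%        9.98  2.07e-03  +0.037
    1     18.03%      129.36  4.51e-20  -0.195
    2      1.63%        4.78  3.10e-02  +0.182
    3      0.92%        5.36  2.25e-02  -0.257
  ...
```

Five components separate the groups at ANOVA p < 0.05; PC1 (18% of the
variance, F = 129) carries most of the discrimination. The annotated
discriminant profile locates that signal on the apatite lattice:

```python
profile = bs.annotate_peaks(bs.discriminant_profile(results), bs.default_apatite())
for two_theta, label, phase in profile.annotations:
    print(f"{two_theta:6.2f} deg  {label}")
```

```
 25.86 deg  (002)
 26.28 deg  unassigned
 28.88 deg  (210)
 31.36 deg  unassigned
 31.81 deg  (211)
 32.31 deg  unassigned
 32.88 deg  (300)
 33.30 deg  unassigned
 34.09 deg  (202)
 39.81 deg  (310)
 42.27 deg  unassigned
 46.69 deg  (222)
 53.20 deg  (004)
```

The extrema of the loading profile fall on the apatite reflections whose
amplitudes and widths differ between the groups — the basal-plane 002/004
and the 310 among them — which is exactly the physico-chemical contrast the
generator encodes.

The same pipeline is available from the shell:

```sh
bonescatter pipeline --out run1 --seed 1       # simulate → preprocess → CV → profile
bonescatter stepstudy --in run1/cohort --out table.csv
```

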