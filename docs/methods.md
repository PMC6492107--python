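# Methods

## Model

The normative model is a feed-forward denoising autoencoder over a fixed
104-dimensional feature vector: 68 Desikan–Killiany cortical-thickness
parcels (mm) and 36 segmentation volumes (mm³). All modelling happens on
z-scored features, using the per-feature mean and *population* SD of the
healthy reference cohort; test cohorts are always scaled with the frozen
reference parameters, never re-fit, so a deviation is measured against the
healthy population's location and spread. The z-scoring also makes mm and
mm³ features commensurable, which is what lets the deviation metric average
over both kinds.

Architecture (defaults): input 104 → h1 = 100 SELU → z = 75 SELU; two
supervised softmax heads branch from **h1** (16-way age over the integer
years 22–37, 2-way sex); decoder input is concat(z, ŷ_age, ŷ_sex) (width
93) → h2 = 100 SELU → linear output 104. SELU layers use LeCun-normal
initialization, the softmax heads and linear output use Glorot-uniform.
Branching the heads from h1 rather than z keeps the covariate predictors
outside the bottleneck they are meant to drain; the decoder receives the
heads' *predicted* probabilities (not true labels) in both training and
inference, so a single consistent graph serves data with or without
labels.

Loss = reconstruction MSE (averaged over batch **and** features, so the
four terms are scale-comparable) + age cross-entropy + sex cross-entropy +
XCov, with per-term weights (default all 1) and an L2 penalty
(coefficient 1e-3) on weight matrices only — biases are excluded, the
standard convention. XCov is the summed squared batch cross-covariance
between latent units and the concatenated head outputs,
½ Σᵢⱼ [ (1/n) Σₙ (zₙᵢ − z̄ᵢ)(ŷₙⱼ − ȳⱼ) ]², computed per mini-batch with the
1/n (population) covariance and the ½ factor; this is one of several
equivalent-in-spirit normalizations and is documented here as this
package's convention. Penalizing covariance with the head *outputs* pushes
age/sex information out of z; the ablation test (XCov weight 0) confirms
latent–age correlation roughly triples without it.

Training: 2,000 epochs by default, mini-batches of 64, data reshuffled each
epoch, final short batch kept. Inputs are corrupted per step with fresh
additive Gaussian noise (SD 0.1 in z-units); the loss always targets the
clean batch. Optimizer is Adam (β₁ = 0.9, β₂ = 0.999, ε = 1e-8) with a
per-epoch exponential decay γ = (lr_final/lr_initial)^(1/(epochs−1)), so
the last epoch uses exactly lr_final (0.05 → 0.0005 by default). Forward
and backward passes are hand-derived NumPy; the test suite verifies every
parameter gradient against central finite differences (including the XCov
and softmax-through-decoder paths).

All randomness in a run (weight init, shuffling, corruption) flows from one
integer seed; identical config + seed + data reproduce the training history
bit-for-bit. A non-finite loss aborts with the epoch and term values.

## Deviation analysis

A subject's deviation metric is the mean of the 104 per-region squared
reconstruction errors (z-scored space); the per-region errors are the
subject's deviation map. Group contrasts use the two-tailed Mann–Whitney
U test: exact null enumeration when n_a·n_b ≤ 400 and the data are
tie-free, otherwise the normal approximation with tie and continuity
corrections (both branches validated against a brute-force rank-enumeration
oracle). Effect size is Cliff's delta, computed by direct pair counting;
for tie-free data it satisfies δ = 2U/(n_a·n_b) − 1. Regional tables are
sorted by |δ| descending and flagged at p < .01 per region — a deliberate
fixed threshold rather than a family-wise correction, because adjacent and
homotopic regions are correlated; the null-calibration test confirms the
per-region false-positive rate sits at ~1%. Group comparisons refuse mixed
dataset labels (site/scanner confounding). A mass-univariate variant
applies the identical machinery to raw feature values, which is how one
demonstrates that covariance-only alterations (visible to the multivariate
model) can be invisible region-by-region.

Summaries report mean ± SD *and* median per group: the rank test compares
distributions, but means are what most readers expect to see.

The direction of an alteration (increase vs decrease) is deliberately not
inferred: the reconstruction error is sign-blind, and comparing patients
against the reference cohort directly would confound site effects.

## Bootstrap model comparison

Both the deviation score and a linear SVM are evaluated by percentile
bootstrap of AUC-ROC (default 1,000 replicates; 95% CI from the 2.5/97.5
percentiles). SVM arm: per replicate, ⌊0.7·n⌋ with-replacement draws form
the training set and the never-drawn subjects the test set; C is chosen on
the training set by stratified 10-fold CV maximizing mean balanced accuracy
over {2ᵉ : e odd, −15 ≤ e ≤ 15} (16 values; ties break toward smaller C,
i.e. stronger regularization; the fold count is capped by the smallest
class). Scores are Platt-calibrated probabilities
(`CalibratedClassifierCV(..., ensemble=False)`); since the sigmoid is
monotone this choice cannot change AUC, and a raw decision-margin option is
exposed. Replicates whose in-bag or out-of-bag set lacks a class are
discarded, logged and redrawn. Features enter the SVM z-scored with the
*reference* parameters so both methods see identical inputs.

Normative arm: per replicate the reference cohort is resampled with
replacement (same size), the autoencoder retrained on the resample, and
every clinical subject scored by the deviation metric — normalizing with
the *original* reference parameters. The resulting CI therefore reflects
training variability around the fixed clinical sample's AUC, not clinical
sampling variability; it is structurally narrower than the SVM's CI and
under a null score it need not cover 0.5. For null checks the
`resample_clinical=True` option additionally bootstraps the clinical
subjects per replicate, which restores coverage of 0.5 under
non-discriminating scores. The headline protocol keeps the fixed clinical
sample.

## Architecture selection

Grid search over symmetric configurations: h1 = h2 from
{10, 25, 50, 75, 100} and z from the same grid with z < h1 (10 candidates),
scored by k-fold CV mean clean-input reconstruction error on validation
folds, each fold re-fitting normalization on its training split. The
selected configuration is the argmin of the emitted CV table.

## Synthetic cohorts

The generator emulates what the method assumes about real regional
morphometry: per-subject features x = baseline + age_slope·(age − midrange)
+ sex_offset·1[male] + loadings·f + ε with standard-normal latent factors f
and independent Gaussian regional noise; age is integer-uniform on 22–37
(matching the 16-class coding, with midrange centring so the baseline is
the mean at the age midpoint) and sex Bernoulli(0.5). The default study
decomposes each feature's variance as ≈45% shared factors (10 factors),
35% regional noise, 15% age, 5% sex, with thickness ≈ 2.5 ± 0.15 mm and
volumes ≈ 5000 ± 750 mm³ so normalization is genuinely exercised.
Structural constants (loading directions, effect signs) come from a fixed
design generator; the run seed drives only subject sampling, so "the study"
does not change identity across seeds.

Patients receive mean shifts expressed in closed-form *marginal-SD* units
(scale-free across the mm/mm³ mix; the closed form is validated against a
200,000-subject empirical SD) in a default set of 8 of the 104 regions
spanning both feature kinds, with 0.8 SD as the default effect size — a
moderate, realistically subtle alteration. Covariance-only pathology is
modelled by substituting the patients' loading matrix (e.g. sign-flipping
selected rows, which preserves marginal variances while reversing the
region's correlations).

What the generator does **not** emulate: site/scanner batch effects, head
motion artefacts, heavy-tailed or skewed feature distributions, clinical
heterogeneity (all patients share one alteration pattern), and
age-by-region nonlinearity. Passing tests therefore demonstrate that the
pipeline recovers the *kind* of structure it models, under Gaussian
assumptions, at the stated effect sizes — not performance on real clinical
data.

## Numerical choices

- Population SD (divide by n) for normalization, floored at ε = 1e-8 with a
  warning for constant features (a constant feature then z-scores to 0).
- Exact vs approximate Mann–Whitney switch at n_a·n_b ≤ 400 and no ties.
- AUC gives half credit to tied scores; Cliff's delta counts ties as zero.
- The 36 segmentation volumes are this package's documented default (28
  bilateral structures as left/right pairs plus 8 midline structures);
  segmentation exports vary across software versions, so the schema can be
  overridden from a JSON file.
- The SVM C grid's published form contains a duplicated exponent; it is
  implemented as all odd exponents −15…15 and is overridable.
- Bootstrap replicates draw per-replicate seeds from a spawning
  `SeedSequence`, so each replicate is independently reproducible from the
  run seed.

## Problem sizes used by the test and acceptance runs

The shipped experiments run at desk scale: reference cohorts of 120–1,000
subjects, 500 training epochs for headline recovery experiments (the
learning curve is flat well before that at these sample sizes), 100
bootstrap replicates with 60–150-epoch retraining per replicate, and 100
simulated studies for null calibration. `scripts/acceptance.py` uses
n = 1,000/100/100, 500 epochs, 50 bootstrap replicates at 100 epochs, and
30 null studies.

One experiment deviates from the method defaults deliberately: the
linear-capacity check trains against a rank-75 PCA oracle on 75-factor
Gaussian data. Because the oracle is unregularized, that run disables the
regularizers that bias the full method away from pure reconstruction
(corruption noise, L2, the supervised and XCov terms) and uses a gentler
Adam schedule (0.005 → 5e-5): the default 0.05 initial rate — tuned for the
full four-term objective — is unstable on the penalty-free objective and
never reaches the linear optimum, while the unmodified default
configuration converges to an L2-dominated equilibrium several times above
the PCA error. With the capacity configuration the network reaches ~0.4×
the PCA reconstruction error (its effective bottleneck is 93 wide: z plus
the two head outputs).

## Known limitations

- The deviation metric is sign-blind and cannot localize direction of
  change; it also conflates mean shifts with covariance alterations.
- The normative bootstrap CI understates total uncertainty (see above).
- Exact Mann–Whitney p-values are only used for very small groups; at
  typical group sizes the tie-corrected normal approximation is reported.
- Training is CPU NumPy: fine for 104-feature tables, not for voxel-level
  input.
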