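# Methods

## Statistical model

Each pure-oil class (cactus seed oil CO, refined sunflower oil SO) is
modeled as a multivariate normal distribution over k = 37 compositional
features in three percent-of-total blocks: 12 fatty acids (% of total
FA), 21 triacylglycerols (% of total TAG peak area) and 4
tocochromanols (% of total tocochromanol content). The model is fitted
by the per-feature arithmetic mean and the unbiased (n−1) sample
covariance. The normality assumption is pragmatic: it makes augmentation
(sampling), fidelity scoring (closed-form KL divergence) and mixture
moment algebra all exact, at the cost of ignoring skewness and bounded
support of real compositions.

Preprocessing mirrors routine compositional reporting: analytical
replicates are collapsed to their arithmetic mean per sample, and
entries below the limit of quantification or not detected are set to
zero at that point (flags are preserved losslessly through CSV I/O so
raw files stay faithful).

### Sampling from a singular covariance

With tens of features and a few dozen samples, the empirical Σ is
rank-deficient; percent-of-total closure makes even the population
covariance singular. Draws are generated as μ + V√λ z with
Σ = VλVᵀ the eigendecomposition, z standard normal, and negative
eigenvalues clipped at zero (tolerance 1e−8 relative; anything more
negative raises an error naming the offending eigenvalue). A
`clip_nonnegative` flag truncates negative simulated values at zero; it
is **off** by default for simulation experiments (the model is the
stated Gaussian, and whether real workflows post-process negatives is
unknown) and **on** when emulating observed tables, where negative
percentages are physically impossible.

The independent-marginal generator draws every feature from its
univariate marginal N(μᵢ, Σᵢᵢ). It deliberately matches first and
second marginal moments while destroying all correlation — the exact
information the full-covariance sampler exists to preserve — and serves
as the weaker reference point in generator comparisons.

## Kullback-Leibler divergence

Fidelity of a simulated distribution N₀ = (μ₀, Σ₀) to an observed one
N₁ = (μ₁, Σ₁) is the closed-form Gaussian divergence

D(N₀‖N₁) = ½ [ tr(Σ₁⁻¹Σ₀) + (μ₁−μ₀)ᵀΣ₁⁻¹(μ₁−μ₀) − k + ln(det Σ₁/det Σ₀) ],

in nats (natural log), direction fixed as simulated‖observed. Because
both covariances are singular in practice, both receive the same
deterministic diagonal ridge ε·mean(diag(Σ))·I before evaluation
(default ε = 1e−6, relative to the matrix's own variance scale). A
deterministic ridge was chosen over random jitter for reproducibility;
applying the *same* ridge to both sides preserves the identity law
D(d, d) = 0 exactly. All terms are computed through Cholesky
factorizations — log-determinants as 2Σ ln diag(L), the trace and
Mahalanobis terms through triangular solves — so no explicit inverse or
raw determinant is ever formed; at k = 37 a naive determinant would
over/underflow.

Divergences against near-singular observed fits are dominated by the
ridge-regularized small eigenvalues; absolute magnitudes therefore
depend strongly on ε and are meaningful mainly for *comparing*
generators and sizes under a shared ε, which is how the package (and
its tests) use them.

## Mixture synthesis

Adulteration at mass fraction r is the feature-wise weighted sum
(1−r)·CO + r·SO. The default design is 7 classes — pure CO, mixtures at
r = 0.01, 0.03, 0.05, 0.07, 0.09, pure SO — with equal sample counts.
Each mixture class blends **fresh, index-paired, independent** draws of
the two pure distributions (pure-class pools are not reused). Under
this pairing the class moments are exactly

E[x] = (1−r)μ_CO + r·μ_SO,  Cov[x] = (1−r)²Σ_CO + r²Σ_SO,

which the tests verify empirically. No renormalization is applied after
blending: a convex combination of blocks that each sum to ~100 already
sums to ~100. The linear blend ignores any matrix effects of real
mixing, which is an explicit modeling assumption, not an approximation
error.

## Classifiers

**Random Forest** — tuned by exhaustive grid search over six
hyperparameters (max_depth, bootstrap, max_features,
min_samples_split, min_samples_leaf, n_estimators), scored by
stratified k-fold cross-validated accuracy on the training split only,
then refit on the full training split. The default grid is compact
(3·2·2·2·2·2 = 96 combinations, 5 folds) and replaceable. Enumeration
order is the declared field order with each list in declared order
(itertools.product, last field fastest); ties keep the first
combination encountered, making the search fully deterministic. A
direct `fit_random_forest` path trains one pre-chosen configuration
without search; scaling experiments use it with a reduced forest
(10 trees, depth 14) so that corpora up to 10⁵ samples/class remain
tractable on a single CPU.

**Neural network** — a fully connected feed-forward classifier: input
width = number of features, ReLU hidden layers, output width = number
of classes, cross-entropy loss, Adam mini-batch optimization
(scikit-learn's MLPClassifier). Randomized search draws the three tuned
hyperparameters — number of hidden layers (1–3), width per layer
(32/64/128), batch size (64/256) — for 20 trials of 50 epochs each,
scores each trial on a stratified 10 % validation split carved from the
training data, and refits the best configuration on the full training
split. Features are standardized with mean/SD from the data being fit
(the forest, being scale-invariant, sees raw features). Training is
deterministic given the seed; each trial derives its own seed from the
master one.

The train/test split is stratified 80/20. Evaluation reports accuracy,
the K×K confusion matrix in the fixed class order CO, 99:1, 97:3,
95:5, 93:7, 91:9, SO, per-class precision/recall/F1 (zero-denominator
metrics reported as missing/NaN, never coerced to 0), and an adjacency
analysis mapping every error to the |true − predicted|
adulteration-percentage distance, banded at ≤2, (2,4] and >4 points.
Pure SO is placed at 100 % for banding so all class pairs have a
defined distance.

## Synthetic ground truth (fixtures)

The fixture module emulates the study's measured data so the pipeline
is testable end-to-end without downloads. Per class:

- **Means**: midpoints of per-feature composition ranges, renormalized
  per block to sum to 100. Ranges for the dominant fatty acids and all
  tocochromanols follow published values for Moroccan cactus seed oil
  and refined sunflower oil (CO: palmitic 11.4–12.9 %, oleic
  13.0–23.0 %, linoleic 54.6–65.4 %, γ-tocopherol 92–97 %; SO: palmitic
  5.6–6.9 %, oleic 28.5–32.7 %, linoleic 54.6–59.1 %, α-tocopherol
  96–97 %). "Up to x %" statements are treated as (0, x). Minor fatty
  acids and all TAG species carry invented but plausible ranges; they
  are synthetic stand-ins with no claim of chemical realism.
- **Covariance**: sd_i = cv·max(μ_i, floor) with defaults cv = 0.08 and
  floor = 0.02 percentage points, capped at half the feature's stated
  range (a spread wider than the range itself would contradict the
  ranges the means come from); correlation is a one-factor matrix with
  a single off-diagonal ρ = 0.3; each block is then closed with the
  oblique projector M = I − w·1ᵀ (w ∝ the block's standard deviations),
  so simulated block sums are exactly 100 and the closure correction is
  absorbed by dominant analytes rather than trace ones. The closure
  makes Σ singular by construction — the same rank deficiency real
  percent-of-total covariances exhibit — which doubles as a standing
  test that downstream code handles degenerate Gaussians.
- **Observed tables**: 27 CO and 10 SO rows (the study's sample
  counts), drawn with non-negativity clipping and ids CO1…, SO1….
- **Real-world-style mixtures**: 33 rows blending randomly chosen
  observed CO and SO parents at the five ratios, all ratios represented
  (largest-remainder allocation), emulating physically prepared
  validation samples.

What the fixtures do **not** emulate: non-Gaussian marginals, batch or
instrument drift, replicate-level noise structure, and any real
covariance beyond the one-factor + closure form. Tests passing on
fixtures therefore demonstrate the correctness of the pipeline's
mathematics and mechanics, not the field performance of the classifiers
on real oils.

## Orchestration and reproducibility

The pipeline runs fixtures → preprocessing → fits → generator
comparison → corpus → split → RF/NN tuning → evaluation, persisting
every intermediate and a manifest (config hash, per-stage seeds,
artifact paths). Each stage's seed is the first four bytes of
SHA-256("master:stage") reduced mod 2³¹, so one master seed controls
the whole run, stages are decorrelated, and any stage can be re-run in
isolation. Reports are serialized with sorted keys; rerunning a config
reproduces the Random-Forest reports byte-for-byte (the network's
reports are reproducible under the same seed contract).

## Default problem sizes

Simulation experiments default to 10³–10⁴ samples per class (up to 10⁶
is supported); moment-law and recovery checks use 10⁵ draws; the
sampling oracle for the divergence uses 10⁶ draws at k = 3; classifier
scaling runs use the reduced fixed forest described above at
10³/10⁴/10⁵ samples per class. These sizes were chosen so the full
validation suite runs comfortably on a single CPU while leaving every
statistical bound several standard errors of slack.

## Known limitations

- Gaussianity is an assumption, not a finding; heavy tails or skew in
  real compositional data will degrade both the simulation fidelity and
  the meaning of the KL divergence.
- KLD magnitudes depend on the regularization ε when covariances are
  singular; only comparisons under a shared ε are interpretable.
- The linear blend ignores chemical interactions of mixing.
- The network implementation targets CPU; no GPU path, early stopping,
  or architecture search beyond the three tuned hyperparameters.
- Real-world-style fixture mixtures are built from the same synthetic
  parents that define the class distributions, so they validate
  mechanics, not generalization.
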