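# Methods

## Network layers

Each subject contributes a T×N ROI time-series matrix with T ≥ 3 timepoints
and N ≥ 3 regions (N ≥ 4 for the high-order layers). The low-order network
(LOFC) is the Pearson correlation matrix of the columns. The topographical
high-order network (tHOFC) correlates, for each pair (i, j), the two
regions' LOFC *profiles* — their rows of the LOFC matrix restricted to
indices k ∉ {i, j}, so each profile has length N − 2. The associated
high-order network (aHOFC) correlates region i's tHOFC profile with region
j's LOFC profile over the same restricted index set; since that raw matrix
is asymmetric it is symmetrized as (A + Aᵀ)/2. Both indices i and j are
excluded from the profiles, so an entry never sees either region's
self-connection or the pair's mutual connection.

The profile correlations are evaluated in closed form from restricted sums
(row sums, row sums of squares and one cross matrix product with the
excluded terms subtracted), which makes a 116-region subject a
milliseconds-scale computation while agreeing with the explicit
profile-construction oracle to 1e−12. Final entries are clipped to [−1, 1]
to absorb last-ulp overshoot.

Degenerate entries — a profile with zero variance after the exclusions, as
happens when a LOFC row is constant — are set to 0 with a logged warning
rather than raising. Undefined correlation is treated as absent
connectivity; this keeps batch runs alive and never affects well-defined
entries. Zero *input* variance (a constant ROI time series) is different:
there the Pearson correlation of the raw data is undefined for every pair
involving that region, so network construction refuses the subject and the
cohort reader rejects it with a named reason.

Diagonals are a convention (1 for LOFC and tHOFC, the symmetrized raw value
for aHOFC) and never enter the features: only the strict upper triangle is
vectorized, in row-major order with 0-based ROI indices. This ordering is
part of the public contract because fused feature columns and reported
discriminative edges are identified by it. At N = 116 the feature vector has
N(N−1)/2 = 6670 entries.

Symmetry checks use an absolute tolerance of 1e−8.

## Feature selection and fusion

Within each cross-validation fold, every edge of every requested layer is
tested with a two-sided two-sample t-test (patients vs controls) computed on
training subjects only. The pooled-variance (Student) form is the default —
the textbook two-sample test — with Welch available behind a keyword. Raw
p-values are thresholded at 0.01 or 0.05 with strict inequality and no
multiple-testing correction: the protocol deliberately screens edges rather
than controlling family-wise error, and the threshold is exposed in
configuration. Edges with zero pooled variance get p = 1 and are never
selected. An empty selection is legal; classifiers refuse to train on zero
features with a message that points at the threshold, and the
cross-validation driver falls back to predicting the training-fold majority
class for that fold (with a warning) so null-calibration experiments are not
killed by an occasional empty fold.

Selected features are concatenated across layers in the fixed order LOFC,
tHOFC, aHOFC, with per-column provenance retained, and z-scored using
training-fold mean/sd (constant columns get sd 1). Standardization
parameters are stored with the fold's model and reused at test time.
Stability reporting intersects each layer's selected sets across all
training folds — the only leakage-free reading of "selected in every round".

## Classifiers

The linear SVM is scikit-learn's `SVC(kernel="linear", C=1)`; its fit is
deterministic given the data.

The domain-adversarial network is a small feedforward architecture
implemented directly on NumPy (fully connected layers, batch normalization,
ReLU, inverted dropout, sigmoid, adam), with backpropagation verified
against finite differences. The feature extractor is one fully connected
layer (input_dim → hidden, default hidden = input_dim/2) with
BatchNorm → ReLU → Dropout(0.5). The label predictor and domain classifier
are identical stacks of two fully connected layers (hidden → hidden/2 → 2)
with BatchNorm → ReLU → Dropout between them and sigmoid outputs. The two
output units are deliberately uncoupled sigmoids rather than a softmax: the
training loss

    L = (1/N_all) Σ_n Σ_c W_c · E(y_nc, ŷ_nc),
    E(y, ŷ) = −[y log ŷ + (1−y) log(1−ŷ)],
    W_c = e^{1/N_c} / Σ_{c'} e^{1/N_{c'}}

weights each class's cross-entropy term, and with complementary
probabilities (a single sigmoid read as (1−p, p)) the two terms are
algebraically equal and the weighting cancels; with independent per-class
units it is effective. Probabilities are clamped to [1e−7, 1 − 1e−7] inside
the loss. Class weights are computed on the training fold only; the rarer
class always receives the strictly larger weight, and equal counts give
uniform weights, in which case the loss equals half the plain per-class
summed BCE.

The gradient-reversal layer between extractor and domain classifier is the
identity forward and multiplies backward sensitivities by −λ. λ is constant
per run (default 1.0); an optional linear 0 → λ ramp over epochs exists but
is off by default. Each optimization step runs a labeled source pass
(extractor + label head) and an adversarial pass (source batch plus a
resampled target batch through the GRL and domain head), accumulates both
gradients and applies one adam step (lr 0.001, default 200 epochs, batch
size 64; single-subject trailing batches are skipped because batch
statistics are undefined).

Determinism and the λ = 0 contract are engineered explicitly: one integer
seed spawns named child streams (extractor/head initialization, shuffling,
label-pass dropout, domain-pass dropout, target resampling), and the
extractor's BatchNorm running statistics advance only on the labeled pass.
Consequently training logs are bit-identical across runs, and with λ = 0
the extractor and label head evolve exactly as a plain MLP trained without
a domain head from the same seed — the property tests assert both at
machine precision.

The held-out site is exposed, unlabeled, to the domain classifier during
training (standard adversarial-adaptation usage); a flag disables this.
Held-out accuracy is recorded every epoch (evaluation mode: running
statistics, no dropout), supporting two reporting senses: *test*, the
held-out accuracy at the epoch of highest training accuracy, and
*best_test*, the maximum held-out accuracy over all epochs. best_test ≥ test
by construction.

## Cross-validation and comparison

Leave-one-site cross-validation holds out each site once; selection,
standardization and class weights are fitted on the remaining sites only.
Per-fold accuracy is plain correct/total in percent; folds aggregate as an
unweighted mean ± sd (sd across folds, ddof 1), with a subject-weighted
pooled accuracy logged alongside. A held-out site with a single diagnostic
class is still evaluated (accuracy remains well-defined); training sites
lacking a class abort the fold with an error. Configurations are compared
with a two-sided paired t-test across per-site accuracies, paired by
held-out site; identical reports return p = 1 by convention, and a constant
nonzero difference (zero-variance pairing) is reported as a certain
direction.

## Synthetic cohorts

The generator emulates the structure of a multi-site case/control
resting-state cohort. A sparse symmetric latent matrix (off-diagonal entries
nonzero with probability `base_density`, drawn uniformly from [−0.6, 0.8])
is projected to the nearest symmetric positive-definite correlation matrix
by eigenvalue clipping at 1e−4 followed by unit-diagonal renormalization;
this is the control group's correlation matrix. The patient matrix adds +δ
(`effect_size`) to the chosen effect edges and re-projects. Projection can
shrink the nominal shift, so `realized_effects` reports the post-projection
difference and all recovery experiments compare against realized, not
nominal, effects. Subject time series are i.i.d. multivariate-normal rows
under the group's correlation matrix.

Site effects have four components, all drawn per site: a per-ROI
multiplicative gain (lognormal, log-sd `site_shift_sd`), a per-ROI additive
offset (normal, sd `site_shift_sd`), an additive sensor-noise amplitude and
a global-signal amplitude (both lognormal with median `site_shift_sd`).
Gain and offset model scanner scaling/baseline but leave Pearson
correlations invariant; the sensor noise attenuates observed correlations
and the shared global signal inflates them, each by a site-specific amount,
so sites are detectable from connectivity features — the nuisance structure
the adversarial classifier is meant to remove — while group structure stays
intact (both groups within a site receive identical perturbations, so null
calibration is unaffected). One seeded generator stream drives latent
structure, site parameters and subject noise in a fixed order, making
cohorts bit-reproducible.

Defaults mirror a ten-site cohort of 1160 subjects (597 patients, 563
controls) at N = 116 and T = 230. The generator does *not* simulate
hemodynamics, temporal autocorrelation, motion, or preprocessing artifacts;
passing tests therefore demonstrate correctness of the statistical pipeline
under a known generative model, not performance on real fMRI.

## Problem sizes in the test and acceptance runs

Tests and the acceptance script run the pipeline at reduced scale chosen to
keep the statistical checks well-powered: networks are verified against
oracles at N ≤ 8; calibration uses 50 zero-effect cohorts of 40 subjects
(N = 10, T = 100, ~2250 null edges, 3-binomial-SE bands); recovery and
classification use 10 cohorts of 100 subjects across 3 sites (N = 20,
T = 150, five injected edges with realized Δr ≥ 0.3); adversarial runs use
the default 200 epochs on a 3-seed subset. The full suite completes in well
under a minute.

## Known limitations

* The feature extractor's depth/width and the training epochs/batch size are
  weakly constrained by the protocol being implemented; the defaults above
  are this package's choices and are exposed in `DannConfig`.
* The adversarial benefit of λ > 0 on held-out-site accuracy is
  cohort-dependent; the package asserts the *mechanism* (λ = 0 equivalence,
  −λ gradients, rising domain loss under adversarial pressure) rather than a
  universal accuracy gain, and reports the measured λ = 1 vs λ = 0
  difference in the acceptance output.
* Accuracies on synthetic cohorts are far above those achievable on real
  multi-site MDD data, where effect sizes are much smaller; the synthetic
  effect sizes are set to make recovery and calibration properties sharply
  testable, not to imitate clinical difficulty.
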