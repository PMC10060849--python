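# brainlayers

Multi-layer functional brain-network construction and multi-site case/control
classification, aimed at resting-state fMRI studies of major depressive
disorder (MDD) and, more generally, at any study that extracts per-subject
ROI time series from a multi-site cohort and asks whether different *levels*
of the connectome carry complementary diagnostic information.

## The method

For each subject with time series `X = [x_1, …, x_N] ∈ R^{T×N}` (T
timepoints, N atlas regions; N = 116 for the AAL atlas) three weighted
networks are built:

* **LOFC** (low-order functional connectivity): `LOFC_ij = corr(x_i, x_j)`,
  the Pearson correlation connectome.
* **tHOFC** (topographical high-order FC):
  `tHOFC_ij = corr(w_i·, w_j·)` over `k ≠ i, j`, where `w_i·` is region i's
  row of the LOFC matrix — two regions are connected when they connect to
  the rest of the brain in the same pattern.
* **aHOFC** (associated high-order FC): `A_ij = corr(tHOFC_i·, w_j·)` over
  `k ≠ i, j`, symmetrized as `W ← (W + Wᵀ)/2` — the cross-level association
  between a region's high-order profile and another's low-order profile.

The strict upper triangle of each N×N matrix becomes an edge-feature vector
(6670 features at N = 116). Per cross-validation fold, edges are screened by
a two-sided two-sample t-test (patients vs controls, training subjects only)
at p < 0.01 or p < 0.05; surviving features from the chosen layers are
concatenated into the multi-layer feature, z-scored with training-fold
statistics, and classified by either

* a **linear SVM** (C = 1), or
* a **DANN** — domain-adversarial neural network: a shared feature extractor
  feeding a label predictor (patient/control) and a domain classifier
  (source sites vs held-out site) through a gradient-reversal layer that
  multiplies backward gradients by −λ, pushing the extractor toward
  site-invariant features. Both heads are two fully connected layers with
  BatchNorm → ReLU → Dropout(0.5) and sigmoid outputs, widths halving per
  layer; losses are binary cross-entropies with class weights
  `W_c = e^{1/N_c} / Σ e^{1/N_c}`; training uses adam at learning rate 0.001.
  The network is implemented directly on NumPy with explicit, seeded
  randomness, so training runs are bit-reproducible.

Generalization is measured by **leave-one-site cross-validation** (LOSCV):
each acquisition site in turn is the held-out test set. Accuracies are
reported in percent as mean ± sd across folds, with two senses for the DANN:
*test* (held-out accuracy at the epoch of best training accuracy) and
*best_test* (maximum over epochs). Configurations are compared with a paired
t-test across per-site accuracies.

Because the consortium data this protocol targets are access-restricted, the
package ships a synthetic multi-site cohort generator with known effect
edges, SPD-projected group correlation matrices, and per-site gain/offset,
sensor-noise and global-signal perturbations, so the whole pipeline is
testable end to end.

## Worked example

```python
from brainlayers import (CohortConfig, SiteSpec, EvalConfig, generate_cohort,
                         build_feature_tables, run_loscv,
                         compare_configurations, realized_effects, summary_frame)

cfg = CohortConfig(
    n_rois=20, n_timepoints=120,
    sites=[SiteSpec("siteA", 17, 17), SiteSpec("siteB", 17, 17), SiteSpec("siteC", 16, 16)],
    effect_edges=frozenset({(0, 1), (2, 3), (4, 5), (6, 7), (8, 9)}),
    effect_size=0.25, site_shift_sd=0.2, base_density=0.1, seed=5,
)
print("realized group differences:",
      {e: round(d, 3) for e, d in realized_effects(cfg).items()})
cohort = generate_cohort(cfg)
tables = build_feature_tables(cohort)

lofc = run_loscv(cohort, EvalConfig(layers=("LOFC",), p_threshold=0.05, seed=2), tables)
combined = run_loscv(cohort, EvalConfig(p_threshold=0.05, seed=2), tables)
print(summary_frame([lofc, combined]).to_string(index=False))
cmp = compare_configurations(lofc, combined)
print(f"paired t-test LOFC vs Combined: t={cmp.statistic:.3f}, p={cmp.p_value:.3f}")
```

prints

```
realized group differences: {(0, 1): 0.238, (2, 3): 0.244, (4, 5): 0.249, (6, 7): 0.246, (8, 9): 0.25}
configuration classifier  p_threshold sense  mean_accuracy  sd_accuracy  pooled_accuracy  n_folds
         LOFC        svm         0.05  test      90.012255     4.443564             90.0        3
     Combined        svm         0.05  test      88.051471     2.670191             88.0        3
paired t-test LOFC vs Combined: t=0.555, p=0.635
```

Reading the output: the nominal +0.25 correlation shift on the five injected
edges survives the SPD projection almost intact (realized Δr ≈ 0.24–0.25);
with 50 patients and 50 controls over three sites, the single-layer LOFC
configuration classifies held-out sites at 90.0 ± 4.4 % and fusing all three
layers gives a statistically indistinguishable 88.1 ± 2.7 % (paired p = 0.64)
— on this synthetic cohort, as in typical real cohorts, the high-order
layers add information but not accuracy.

The same flow is available from a shell:

```bash
brainlayers simulate --config examples/toy.yaml --out run/
brainlayers evaluate --config examples/toy.yaml --manifest run/manifest.csv --out results/
brainlayers compare  --folds-a results/folds_LOFC_svm_p0.05.csv \
                     --folds-b results/folds_Combined_svm_p0.05.csv
```

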