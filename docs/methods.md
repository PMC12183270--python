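# Methods

`mag` classifies subjects as major depressive disorder (MDD) patients or
healthy controls (HC) from resting-state fMRI ROI time series, using an
ensemble of graph attention networks (GATs) — one per brain parcellation
atlas. This note records the model, its assumptions, the tunable parameters,
and the design choices made where the design was genuinely open.

## Pipeline

Input is one T×N time-series matrix per subject per atlas (default T=140;
atlases Dose/160, AAL/116, CK/200, HO/112 ROIs) plus a manifest with site,
diagnosis (MDD=1, HC=0), age and sex. Stages, in order:

1. **ComBat harmonization** of multi-site batch effects.
2. **Stratified splitting** (single 80/10/10 split, or stratified k-fold
   with an inner 8:1 train/validation re-split).
3. **Class-wise SMOTE** doubling of training and validation sets.
4. **Connectome construction**: Pearson correlation → Fisher z → KNN graph.
5. **Per-atlas GAT training**, one classifier per atlas.
6. **Ensembling**: majority vote, probability sum, accuracy-weighted sum.
7. **Metrics**: accuracy, sensitivity, specificity, precision, F1 per fold,
   mean ± sample SD across folds.

All randomness descends from one root seed through named substreams
(`mag._rng.substream`), so any stage re-run in isolation with the same seed
reproduces its output bit-for-bit.

## Harmonization (parametric empirical-Bayes ComBat)

Each (atlas, time point, ROI) entry is one feature observed across subjects:

    y = α + Xβ + γ_site + δ_site · ε

with X = (standardized age, sex). α, β are fit by pooled least squares;
residuals are standardized by the pooled **within-site** SD (the between-site
location spread belongs to γ, not to the scale — pooling the raw residual
variance measurably destroys the multiplicative-effect estimate); per-site
means γ̂ and variances δ̂² of the standardized data are shrunk by parametric
empirical Bayes (normal prior on γ, inverse-gamma on δ², moment-matched
hyperpriors, iterated conditional updates to tolerance 1e-4). Harmonized
data remove γ*, δ* and restore the covariate model.

Notes and caveats:

- Treating each *time point* as a feature is unusual — time points are not
  anatomically aligned across subjects — but it is the form the pipeline is
  specified in. Site variances are estimated with ddof=0, matching the
  pooled ddof=0 scale, so a fit on batch-free data is exactly neutral.
- γ is identifiable only up to a per-feature location shift (the intercept
  absorbs the mean site effect); recovery tests therefore compare against
  mean-centered true γ. δ* is a scale *relative to the pooled SD*, so
  recovery compares against true δ normalized by its per-feature RMS
  across sites.
- Harmonization is fit on the full cohort before splitting, mirroring the
  protocol order; see README for the leakage caveat.
- Zero-variance features are flagged and passed through. Sites need ≥ 2
  subjects; unseen sites at apply time are an error (no reference-batch
  mode). Non-parametric ComBat, ComBat-GAM and longitudinal variants are
  out of scope.

## Oversampling (row-wise time-series SMOTE)

For each real seed sample of a class, one of its k=3 nearest same-class
neighbors (Euclidean distance on the flattened concatenation of all atlases'
matrices, so one neighbor serves every atlas) is drawn uniformly; for each
time-point row a gap ~ U(0,1) gives

    Z_t = X0_t + (X_t − X0_t) · gap_t.

The gap is shared across the ROIs of a row and across atlases, preserving
within-row spatial structure; a single-gap-per-sample mode is available
(`gap_mode="per_sample"`). One neighbor is drawn per synthetic sample, not
per row. At multiplier 2 every class count doubles exactly. Synthetic
records carry `syn:`-prefixed ids, the seed's site and label, and an
`is_synthetic` flag that bars them from test sets; consequently every
synthetic entry is elementwise inside its parents' convex hull. A paired
t-test over all T·N entries (`validate_synthetic`) checks distributional
consistency; identical samples return p=1 by convention, a constant nonzero
shift returns p=0.

## Connectomes and graphs

Pearson correlation between ROI columns (constant columns get zero
correlation with a warning; T ≥ 3 required), Fisher z = atanh with
correlations clipped to ±(1−1e-7), diagonal forced to 0. The KNN graph
connects each node to the k nodes of largest |z| (ties toward the lower
index), union-symmetrized, so every degree is in [k, n−1]; edge weight is
the Fisher-z value; node i's feature vector is row i of the z-matrix.
"Nearest" by |z| is a design choice (strong negative coupling is as
informative as positive); a Euclidean-on-rows mode exists
(`knn_metric="euclidean"`). k is not dictated by the protocol; default
`knn_k=10`.

## GAT classifier

Three attention layers, K=4 heads concatenated with head width 16 (layer
width 64 — "64 hidden units" is read as total layer width; per-head width is
a config knob via `hidden_units`/`n_heads`), LeakyReLU (slope 0.2, the GAT
convention) both inside attention and as the layer nonlinearity, dropout 0.5
on node features before each layer, global average pooling, affine head,
softmax. Attention per layer/head with a = [a_src ∥ a_dst]:

    e_ij = LeakyReLU(a_srcᵀWh_i + a_dstᵀWh_j),  j ∈ N(i) ∪ {i}
    α_ij = softmax_j(e_ij),   h_i' = σ(Σ_j α_ij W h_j)

Self-loops are added inside the layer. KNN edge *weights* are deliberately
not fed into attention — the attention mechanism is a function of node
features only — but are retained in exports. Head averaging (instead of
concatenation) is implemented behind `head_combine="average"` and unused by
default.

The network, backward pass and Adam optimizer are implemented in NumPy;
minibatches are disjoint unions of graphs so a whole batch is one vectorized
pass, and gradients are exact (finite-difference-verified in the tests).
Training: minibatch Adam (batch 16, lr 1e-3, coupled L2 weight decay 5e-4),
cross-entropy loss, early stopping on validation loss (patience 20, max 200
epochs — the epoch budget is a package policy, the protocol does not state
one), parameters restored from the best-validation epoch; `val_accuracy` is
recorded there and later drives ensemble weights and tie-breaks.
Initialization is uniform fan-in U(±1/√fan_in) from a named substream.
Divergent configurations (non-finite loss) abort training with validation
accuracy 0, which makes grid search robust to sabotaged cells. The default
grid is lr × weight-decay × batch × dropout = {1e-2,1e-3,1e-4,1e-5} ×
{1e-3,5e-4,1e-4,5e-5} × {8,16,32,64} × {0.2,0.3,0.4,0.5}; ties break toward
the lower learning rate, then lower weight decay.

## Ensembling

Hard votes are softmax argmaxes (exact probability ties go to MDD, the
sensitivity-favoring choice). Majority vote breaks 2–2 ties with the vote of
the model with the highest validation accuracy; accuracy ties fall back to
the fixed atlas order (Dose, AAL, CK, HO). Weighted sum uses
w_j = Acc_j / ΣAcc_i on softmax outputs; the "sum" method is its
uniform-weight special case, an identity the tests assert exactly.

## Splits and metrics

The 80/10/10 allocation per class is: test = ceil(0.1·n); val = test−1 when
0.1·n is integral, else floor(0.1·n); train = remainder. This is the unique
simple rule reproducing the reference cohort's printed counts
(810 → 81/80/649, 753 → 76/75/602, hence 157 real test samples and — after
doubling SMOTE — 2,502 training and 310 validation samples). Stratified
k-fold partitions only real subjects; within each iteration the nine
training folds are re-split 8:1 per class into train/validation and then
oversampled, the only composition consistent with a real-only test set plus
per-fold validation accuracies for the ensemble weights. Metrics treat MDD
as positive; division-by-zero guards return 0 with a warning; fold SDs use
the sample (n−1) convention; best fold = argmax accuracy, ties to the lowest
index. Model comparisons use the equal-variance two-sample t-test (Welch by
flag), p=1 by convention for identical zero-variance inputs.

## Synthetic cohorts

The generator emulates what the pipeline must handle: per-(t, ROI) additive
γ ~ N(0, site_gamma_sd²) and multiplicative δ ~ U(site_delta_range) site
effects, age/sex covariate effects, observation noise, and — crucially — a
class signal injected in *correlation* space: latent inter-ROI correlation
matrices from a block/community model (5 modules; within 0.35, between
0.05), with a random 20% of between-module pairs shifted by `class_effect`
in the MDD class, then nearest-SPD-repaired (eigenvalue clipping + diagonal
renormalization). A mean-space signal would be erased by Pearson centering;
correlation-space injection exercises the actual discriminative pathway.
Ages are N(34, 12²) truncated to [18, 65], sexes Bernoulli(0.5), labels
balanced per site. Defaults (16 sites, 25 subjects/site/class, T=140, the
four reference atlases) mirror the multi-site study conditions.

What the generator does **not** emulate: BOLD hemodynamics, temporal
autocorrelation (rows are i.i.d. in time), head motion, site-by-class
confounding, or realistic effect sizes. Passing tests therefore demonstrate
the pipeline's correctness and its ability to exploit connectivity
differences — not clinical-grade performance on real rs-fMRI.

## Benchmark problem sizes

The end-to-end learning benchmark (`mag.benchmark`) uses the reference
parcellations scaled down about fourfold (Dose 40, AAL 29, CK 50, HO 28
ROIs), T=80, 120 subjects over 3 sites, class_effect 0.6 on 20% of
between-module pairs, and 15 training epochs — chosen once so the full
4-atlas × 20-seed protocol runs in minutes on a single CPU core. On these
conditions each single-atlas GAT reaches well above 70% test accuracy and
the majority-vote ensemble matches or exceeds the mean single-atlas
accuracy, the qualitative pattern the ensemble design targets.

## Known limitations

- Per-time-point ComBat features inherit the protocol's anatomically
  unaligned-feature assumption; a per-ROI-stream variant would be a natural
  extension.
- Full-cohort harmonization before splitting leaks test-set distributional
  information (documented, faithful to the protocol).
- The NumPy GAT is CPU-only and single-threaded beyond BLAS; it is sized
  for hundreds of graphs with ≤ a few hundred nodes, not for GPU-scale
  datasets.
- No multiple-testing correction across the per-metric t-tests (by design).
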