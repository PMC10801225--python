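# Methods

This note records what `popgraphx` computes, the modeling choices the
package makes on its own authority, and the limits of the synthetic
cohort. All symbols refer to the code in `src/popgraphx/`.

## 1. Problem and data model

The package classifies subjects into three cognitive-status classes —
NC (normal cognition), MCI (mild cognitive impairment), AD (Alzheimer's
disease) — from 13 per-subject features in five modality groups
(demographic, imaging, cognitive, neuropsychological, biomarker; see
`features.py`), and explains each individual prediction by
decomposition (occlusion) at the feature, modality-group and
graph-edge level.

Real multimodal dementia cohorts are access-restricted, so the package
ships a synthetic generator (`synthetic_cohort.py`) parameterized by
published class-conditional statistics: per-class means/SDs for the ten
continuous features, per-class category counts for gender and
amyloid/tau positivity, and class sizes 754/1095/363 (2,212 subjects in
total). Everything downstream runs identically on a real cohort CSV
with the same column layout.

### Generator details

* Continuous features are drawn from **moment-matched truncated
  normals**: the parent location/scale are solved (scipy `optimize.root`
  on the truncated-moment equations) so that the *bounded* distribution
  reproduces the target mean and SD. Naively truncating N(mean, sd)
  would bias both moments whenever an instrument bound sits within a
  few SDs of the mean.
* **Censored-normal fallback.** For ceiling-hugging features no
  truncated normal attains the published moments at all — e.g. MMSE in
  NC (29.1 ± 1.07 on a 0–30 scale): the truncated family's SD caps
  near 0.9 for that mean. There the generator moment-matches a
  *censored* normal (`clip(N(loc, scale))`), whose probability mass at
  the bound is exactly the ceiling pile-up such screening scores show
  in practice. The closed-form censored moments are in
  `_censored_moments`.
* Categorical features are per-class Bernoulli draws over the encoded
  codes (gender: Male=1/Female=2; biomarkers: Positive=+1/Negative=−1).
  The published amyloid/tau count pairs are orientation-ambiguous; the
  default reading makes AD predominantly biomarker-positive (the
  clinically plausible one) and `CohortSpec.biomarker_counts_positive_first`
  flips it.
* An optional Gaussian copula (`CohortSpec.correlation`) imposes
  within-class correlation on the continuous block; the default is
  independence, because only marginal moments are published. See
  section 7 for the consequences.
* `inject_artifacts` corrupts a cohort reproducibly with missing cells
  and class-wise out-of-band outliers to exercise the cleaning stage.

## 2. Preprocessing

`clean_features` runs a **single pass** per class and per continuous
feature: values strictly outside the class-wise [5th, 95th] percentile
band of the original column, and missing values, are replaced by a
centered moving mean of window length 8 (four rows either side, clean
cells only, widening when the window holds none). Missing categoricals
take the class mode. Note that single-pass percentile trimming is not
idempotent on generic continuous data — replacing the tails moves the
percentiles, so a second pass would flag a fresh ~10% of cells; the
shipped behavior is the single pass, and the test suite documents both
facts.

`split_dataset` assigns 80/10/10 train/validation/test **stratified by
class, before any normalization**, so no test statistics leak into
scaling. `standardize` then z-scores **all 13 columns** with
train-partition statistics only.

Standardizing the three categorical codes (not just the continuous
features) is a deliberate package choice: the explanation operator
replaces an occluded value by 0, and with uncentered codes (e.g. gender
1/2) occlusion would extrapolate to a nonexistent code 0 — inflating
the decomposition influence of categoricals by several-fold relative to
their Shapley attributions. After centering, "occluded" coincides with
"at the train mean", the natural reference. Original-unit values stay
in the cleaned table for display.

## 3. Population graph

For each cognitive measure (memory, executive function, language
composites) the pairwise similarity is
`S[h,w] = 1 − |v_h − v_w| / max_pairwise_distance`. The three matrices
are averaged, min-max rescaled over the off-diagonal, and thresholded:
weights below `edge_threshold` become non-edges (no significant
similarity). The GCN consumes the self-looped renormalization
`A_tilde = D_hat^{−1/2} (A + I) D_hat^{−1/2}`.

**Default `edge_threshold = 0.95`.** At a 0.5 threshold the
min-max-rescaled similarity distribution keeps ~88% of all pairs (mean
degree ≈ 1950 of 2212); the self-loop weight then collapses to ~5·10⁻⁴,
predictions become independent of a node's own features, occlusion
influences drop to ~10⁻⁴ and the entire explanation framework
degenerates. 0.95 yields mean degree ≈ 45 with single-digit same-class
neighborhoods at weights > 0.96 — the regime the explanation method
needs (and the neighborhood scale the method was described at). The
threshold remains a constructor/config knob.

## 4. Classifier

A two-layer spectral GCN, `H_{l+1} = relu(A_tilde H_l W_l)`, widths
13 → 32 → 3, softmax head; a residual `+ H_l` is applied whenever layer
widths match (never with the default widths; a width-13 hidden layer
that makes the raw-input residual fire destabilizes training and was
rejected). Training is transductive full-batch: cross-entropy on train
rows only, 100 epochs of Adam at lr 0.01, validation accuracy every 5
epochs with best-validation checkpointing. Forward, backward and Adam
are hand-written numpy (the environment ships no autograd framework),
which keeps runs bit-reproducible from a seed; a full 2,212-node run
takes ≈ 3.5 s on one CPU.

### Fast single-node evaluator

Explanations and Shapley sampling evaluate the model under thousands of
variants of *one* node's feature row. `node_class_probs_for_rows`
exploits that only that row varies: with the node's own contribution
removed, each neighbor's hidden pre-activation is affine in the
variant's projected activation α, so per hidden unit the aggregated
relu sum `Σ_j w_j · relu(z_j + c_j α)` is piecewise linear in α.
Sorting the m breakpoints once and keeping prefix sums makes each query
O(h log m). The evaluator is exact (it matches the full forward to
~1e-15; the tests assert 1e-10) and makes 2,000-permutation Shapley per
node run in ~0.2 s. Architectures outside the two-layer no-residual
case fall back to a loop over full forwards.

## 5. Explanations

For node x with predicted class y\* (runner-up y′ gives the
counterfactual reading):

* **Feature** influence: `Var_i(y|x) = p(y|x) − p(y|x∖T_i)` with the
  feature's term omitted from every weighted sum (equivalently zeroed,
  see section 2).
* **Group** influence: all features of one modality occluded at once.
* **Edge** influence: the node's edges to all neighbors of one class
  zeroed symmetrically, adjacency renormalized (degrees change), and
  the probability drop measured.

Because probabilities sum to one, the three class-wise variations of
any occlusion sum to zero — probability lost by the predicted class is
gained by the others, which is what makes the same numbers readable
factually (toward y\*) and counterfactually (toward y′). The test
suite asserts this conservation to 1e-9.

Display products: influences normalized to mean absolute magnitude 1;
clinical discretization (published GDS and MMSE cutoffs; other
continuous features binned by signed SD distance from the pooled mean,
sign-flipped for lower-is-worse features); deviations from same-gender,
±5-year healthy (NC) references; and template sentences for features
whose normalized influence exceeds a floor (default 0.25).

## 6. Evaluation suite

* **Stability** (`stability_table`): for an anchor node, same-class
  neighbors at decreasing edge-weight thresholds; each member's
  normalized own-class influence vector; per-feature |max − min| across
  the neighborhood. Because the default graph zeroes weights below
  0.95, thresholds below that would all see identical neighborhoods —
  `neighbor_graph` lets callers identify neighbors on a
  looser-threshold graph while influences still come from the model
  graph (the CLI does this automatically).
* **Shapley agreement** (`method_agreement`): Shapley attributions of
  the predicted-class probability with train rows as the background
  distribution. Exact enumeration (≤ 20 features, averaged over all
  background rows) doubles as the oracle for the seeded
  permutation-sampling estimator (each permutation paired with one
  background row). Per node, both methods' vectors are scaled to mean
  |·| = 1 before pooling — raw pooling lets magnitude heterogeneity
  across nodes (confident nodes have ~10⁻⁴ influences under both
  methods) dominate the correlation; per-node agreement is the
  quantity of interest, and pooled r stays invariant to positive
  per-node rescaling of either method.
* **Modality ablation** (`modality_ablation`): retrain per feature
  subset per seed; the graph keeps the cognitive measures unless those
  are themselves removed, in which case it falls back to the retained
  features (with a loud warning).

## 7. Known limits of the synthetic cohort

Two ordinal expectations from the original study do **not** reproduce
on the synthetic cohort, and the acceptance suite reports them as
honest failures rather than weakening the assertions:

1. *Biomarker ablation*: removing the biomarker group changes mean test
   MCF by ~0.01 points over 10 seeds — a tie. With only marginal
   moments published, features are conditionally independent given the
   class, and the cognitive + neuropsychological block already carries
   nearly all class signal; the real-data gap reflects correlation
   structure the printed table cannot encode.
2. *Categorical stability*: gender and tau neighborhood-stability
   distances exceed MMSE's, but amyloid positivity is nearly redundant
   with tau under the published proportions, gets ~zero model
   influence, and so shows ~zero variation, dragging the categorical
   aggregate just below MMSE.

The decisions ledger (kept outside the package) records the frozen
protocols and measurements for both.

## 8. Reproducibility

A single run seed fans out to per-stage derived seeds
(`pipeline.stage_seed`: cohort, split, model, Shapley; all < 2³¹), so
stages are independently reproducible and changing, say, the Shapley
seed does not perturb the cohort. `scripts/acceptance.py --seed S --out
F` regenerates the three acceptance-target values from scratch: five
full pipeline runs (seeds S..S+4) for the median accuracy (t1) and
macro-F1 (t3), and sampled-Shapley agreement on the first run's model
(t2). With seed 1: t1 = 88.29 %, t2 = 0.977, t3 = 90.16 % in ~30 s on
one CPU.
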