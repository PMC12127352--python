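# Methods

## Setting

Few-shot classification over a frozen backbone: an N-way-K-shot *episode*
draws N classes and K labeled support samples per class from a labeled
embedding set, plus q query samples per class. Each class is represented by
its prototype c_k, the mean of its support embeddings; a query z is
assigned to argmin_k d(z, c_k) with d the Euclidean distance (cosine
distance 1 − cos∠ is available as an alternative metric). Accuracy is the
fraction of correctly labeled queries; precision, recall and F1 are
computed per class and macro-averaged (equal class weight; a zero
denominator contributes 0 with a warning). Macro averaging is the natural
convention here because episodes are class-balanced by construction.

Nothing in the package trains anything: both methods below operate on
fixed embeddings.

## Layer scoring (FAS)

For the embeddings of layer *l* (dimension n, M samples, N classes with
class means μ_i and global mean μ — the count-weighted mean over all
samples, so unbalanced class sizes are handled and the balanced case
reduces to the textbook formula):

- within-class variance  σ²_w = (1/M) Σ_i Σ_j ‖x_ij − μ_i‖²  (squared L2),
- between-class variance σ²_b = (1/N) Σ_i ‖μ_i − μ‖²         (squared L2),
- mean between-class distance D̄ = 2/(N(N−1)) Σ_{i<j} ‖μ_i − μ_j‖
  (plain, unsquared L2 — it is a distance, not a variance; a
  `dbar_squared` switch selects the squared reading),

combined as **FAS = σ²_b / σ²_w + D̄ / √n**. The variance ratio is
dimensionless; the distance term is scaled by √n so layers of different
width are comparable (per-coordinate displacements of equal size produce
L2 norms growing like √n). n is the feature dimension by default; a
`scale_by="count"` switch substitutes the sample count for users who read
the normalization as a standard-error correction instead. Both readings
are defensible; dimension is the default because it is the only quantity
that actually differs between layers of one dataset.

Numerical choices: all statistics in float64; σ²_w is floored at ε = 1e-12
in the ratio (collapsed features trigger a warning rather than an
infinity); the best layer is the FAS argmax with ties broken toward the
*larger* layer id (deeper layer preferred — deterministic and in line with
the usual preference for later features when the score cannot
distinguish).

The score is invariant to sample order, class relabeling and any common
orthogonal transform; multiplying all features by α leaves the ratio term
unchanged and scales the distance term by exactly α. These invariances,
plus equivalence with a naive double-loop implementation to relative
1e-10, are enforced by tests.

## Calibration (PDFC)

Inputs: an episode, a *reference bank* P of source-domain feature vectors,
and hyperparameters (m, λ, γ). Per episode (the procedure does not depend
on the queries, so it runs once per episode, not per query):

1. Prototypes are the per-class support means (K = 1 reduces to the single
   support vector; K > 1 averages first).
2. For each class i, the m bank rows nearest (L2) to its prototype s_i are
   averaged into a reference centroid c_i. Distance ties at the m-th
   neighbor go to the lower row index. The centroid is a mean of feature
   *vectors*; m defaults to 10 and is a first-class hyperparameter.
3. Among all N centroids, the two nearest to s_i — c_a (nearest) and c_b
   (second; ties to the lower class index) — define the target point
   T = (1−λ)·c_a + λ·c_b. λ is not clamped to [0,1]: the Bayesian search
   range extends to 10, permitting extrapolation along the line. The
   class's own centroid is *not* excluded from the candidates; it usually
   is the nearest, which pulls the prototype toward its own source-domain
   region. An alternate neighborhood rule (`neighbor_mode="b"`: for class
   i, the two *prototypes* nearest centroid c_i designate the pair) is
   selectable; mode "a" is the default.
4. s_i moves exactly γ units along the unit vector toward T:
   s_i + γ·(T−s_i)/‖T−s_i‖. Overshooting past T is allowed. If
   ‖T−s_i‖ < 1e-12 the direction is undefined and s_i stays put.

γ = 0 is an exact identity (bitwise-equal predictions to the uncalibrated
classifier), and every calibrated prototype lies exactly γ from its
original or has not moved — both are tested invariants, as is translation
equivariance of the whole chain.

### What calibration actually does on the synthetic conditions

The covariate-shift generator displaces every target sample by one global
bias vector b. A global bias cancels identically in nearest-prototype L2
distances (support and queries carry the same offset), so the uncalibrated
baseline is unaffected by b, and the measurable benefit of calibration on
these conditions comes from *prototype denoising*: the centroid of m
nearest bank vectors is a far less noisy class representative than a
single support shot, and moving the prototype toward it shrinks prototype
variance — the dominant error source at K = 1. This mechanism operates
with or without shift; the bias only perturbs neighbor selection (slightly
*reducing* the gain in the shifted case). Consequently the no-shift
control shows a comparable accuracy gain rather than a null one, and the
corresponding zero-gain check in the acceptance suite fails by design of
the scenario, not by implementation error; it is kept as an honest record
of that tension. On real cross-domain embeddings, where source and target
geometries differ in more than a translation, both denoising and genuine
shift correction contribute.

## Hyperparameter search

The objective is episode-set mean accuracy computed on a *fixed* episode
seed, so all trials are compared on identical tasks (removes sampling
noise from the comparison).

- **Grid search**: every lattice point of [0,1]² with steps 0.1 (λ) and
  0.2 (γ), endpoints included; exhaustive argmax, ties to the first point
  in row-major (λ outer) order.
- **Bayesian optimization**: Gaussian-process surrogate (constant × Matérn
  5/2 + white-noise kernel, inputs scaled to the unit square, targets
  standardized) with the Expected Improvement acquisition maximized over
  2000 random candidates per iteration; a scrambled-Halton initial design
  of 10 points counts toward the iteration budget (default 100
  evaluations). Wide positive ranges such as [10⁻³, 10¹] are searched in
  log10 space. The returned optimum is always the best *observed* trial,
  never a surrogate prediction; non-finite objective values are recorded
  as failed trials and skipped. Deterministic under a fixed seed.

## Evaluation protocol

`run_evaluation` executes `runs` independent runs of `episodes_per_run`
episodes (defaults 20 × 1000, matching the convention of averaging 20
repetitions of 1000 sampled tasks). Run r draws from the substream
`SeedSequence((seed, r))`, so runs are reproducible individually and
jointly. Classes, then samples, are drawn uniformly without replacement;
support and query indices are disjoint. q defaults to 15 queries per class
(a protocol constant the evaluation convention leaves open). Accuracy mean
and standard deviation are over episodes; macro metrics pool all query
predictions. An optional calibrator closure transforms each episode's
prototypes before classification.

## Synthetic generator

Emulates three things and no more:

- **Gaussian class clusters**: class means at radius `between_scale` along
  deterministic maximally spread unit directions (a seeded random
  orthonormal basis, completed by normalized Gaussian draws when classes
  exceed dimensions), isotropic within-class noise of σ = `within_scale`.
- **Layer series**: layers drawn at `between_scale × separability[k]` and
  dimension `dims[k]` with one shared label vector; the designed
  separability argmax is recorded as ground truth.
- **Shift pairs**: a reference bank from the base clusters plus a target
  set displaced by one fixed global bias of exact norm `bias_norm`
  (optional extra isotropic noise).

Defaults are the package's study conditions: 10 classes × 50 samples,
dim 32, σ_within = 0.3, mean radius 0.9 (= 3σ, a mid-range 5-way-1-shot
regime comparable to reported embeddings of harder field datasets), bank
of 30 vectors per class, bias 0.9 = 3 × σ_within. The unit scale is
deliberate: γ is an absolute step in feature units and the standard tuning
grid spans [0,1], so the emulated embeddings must live on unit-scale
geometry for those ranges to be meaningful.

What the generator does *not* emulate: anisotropic or class-dependent
covariance, heavy-tailed activations, non-linear (beyond translation)
source/target warps, and label noise. Passing tests therefore demonstrate
correctness of the algorithms and their stated invariants, not performance
on real leaf imagery; the image extractor exists precisely so users can
bring real backbones and datasets.

## Problem sizes used in the shipped checks

Layer-concordance checks use 200 episodes per layer over 20 series seeds
and 100 selection trials; calibration checks tune on 200 fixed episodes
over the 66-point grid and compare at 500 episodes; the protocol check
runs the full 1000 × 20. These sizes give stable statistics (binomial SE
of an accuracy mean over 500 episodes is ≈ 0.5 points) while keeping the
whole suite fast on one CPU.

## Known limitations

- The real-backbone adapter is a stub requiring a user-installed deep
  learning runtime; only the deterministic toy backbone is exercised in
  tests.
- FAS's dimension scaling makes scores comparable across layers of one
  bank, not across datasets.
- With m approaching the bank size, all reference centroids collapse
  toward the bank mean and the calibration direction degenerates; m is
  assumed small relative to per-class bank density.
- The GP/EI search assumes a smooth, low-noise objective; with very noisy
  objectives (few episodes per trial) the fixed-episode-seed design is
  essential.
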