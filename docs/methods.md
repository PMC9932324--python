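# Methods

## Problem and pipeline

The package classifies subjects of a multi-site resting-state cohort as
patients (ASD) or controls from the covariance structure of their ROI
time series.  The pipeline is:

1. **Connectivity.**  Each subject's T × N time series (N = 39 ROIs by
   default) becomes an N × N connectivity matrix: Pearson correlation,
   partial correlation (negated, normalized precision entries), or the
   tangent-space parametrization log(G^{-1/2} Σ G^{-1/2}) at the Karcher
   mean G of the *training* covariances.  Subject covariances use
   Ledoit–Wolf shrinkage on standardized series: at T ≈ 150, N = 39 the
   raw sample covariance is ill-conditioned and the matrix logarithm
   needs a safely SPD input.
2. **Graph.**  Connectivity becomes a weighted undirected graph on the
   ROI nodes.  Negative correlations are rectified with |·| by default
   (random-walk transitions need nonnegative weights; under- and
   over-connectivity are treated as equally informative edge strength).
   Optional top-density sparsification with lexicographic tie-breaks;
   the default keeps the full matrix.
3. **Node embeddings.**  Per-subject, unsupervised:
   - *DeepWalk / node2vec* — second-order biased random walks (return
     parameter p, in–out parameter q; p = q = 1 reduces exactly to the
     first-order weighted walk) feeding skip-gram with negative
     sampling (SGNS).
   - *struc2vec* — structural distances w_k(i, j) accumulated over
     k-hop degree sequences compared by dynamic time warping with cost
     max(a,b)/min(a,b) − 1; walks are run on complete layer graphs with
     transition weights exp(−w_k), so structurally similar nodes
     co-occur.  Walking proportional to the accumulated *distance*
     would attract dissimilar nodes; the similarity transform restores
     the method's intent.
   - *AWE* — per-node empirical distributions over anonymized walk
     patterns (node identities replaced by first-occurrence indices).
     The number of patterns of edge-length l follows the Bell numbers
     (1, 2, 5, 15, 52, 203 for l = 1..6); the default 128-dimensional
     vector concatenates the complete distributions for l = 4 (15) and
     l = 5 (52) with the 61 lexicographically-first l = 6 types.
4. **Graph2Img (scenario s3).**  Per-subject PCA of the embedding to 4
   components (deterministic sign convention: the largest-magnitude
   loading of each component is positive), then 2-D binning of
   (PC1, PC2) and (PC3, PC4) onto two r × r grids (r = 10).  Bin bounds
   are min–max over the *training* subjects' scores; test outliers clip
   into edge cells.
5. **Classifier.**  A LeNet-style CNN: conv(64) → ReLU → 2×2 max pool →
   conv(96) → ReLU → 2×2 max pool → dense 120 → dropout(keep 0.8) →
   ReLU → dense 84 → dropout → ReLU → dense 2 → softmax.  Kernels are
   5×5 when the input height is ≥ 20 (the 39 × d scenarios) and 3×3
   otherwise (the 10 × 10 scenario).  Cross-entropy, Adam (lr 1e-3),
   batches of 16.  The CNN and the SGNS trainer are reference NumPy
   implementations — vectorized, single-threaded, deterministic under a
   fixed seed; convolutions use im2col + BLAS matmuls and backprop is
   verified against numerical gradients.

Three input scenarios: s1 = one channel, the N × d embedding of a
single method (d = 25 node2vec, 64 struc2vec, 128 AWE); s2 = three
channels, node2vec at (p, q) = (1, 1), (1, 4), (4, 1), d = 25; s3 = two
channels, the 10 × 10 Graph2Img pair.

## Cross-validation and metrics

Positive class is ASD.  Accuracy, precision = TP/(TP+FP), recall =
TP/(TP+FN) and the F-score — computed both as TP/(TP + (FP+FN)/2) and
as 2PR/(P+R), with the identity asserted — are reported per fold and as
unweighted means.  Two schemes: label-stratified k-fold (site-blind)
and leave-one-site-out (LOSO), the measure of cross-site
generalization.  Every fold re-fits all data-dependent statistics
(tangent reference, Graph2Img bounds, per-channel z-scoring) on
training subjects only; each fitted object records the subject ids it
touched, and the harness refuses to run if any fitted statistic saw a
test subject.  Per-subject embeddings depend only on that subject's own
graph and a fixed seed, so they are memoized across folds without
leakage.

## Synthetic study conditions

The generator emulates the relevant features of a multi-site two-class
resting-state cohort at desk scale:

- **Base covariance**: a modular N × N correlation matrix (within-module
  correlation 0.45, between 0.12, 4 modules) mimicking modular
  resting-state structure.
- **Class effect**: δ added to 20 randomly designated between-module
  edges of the patient covariance (between-region over-connectivity).
  SPD is restored by diagonal loading, which leaves the designed edge
  increments exactly δ — eigenvalue flooring would distort them by up
  to ~0.07 at δ = 0.4.
- **Site effect**: per site, the covariance is blended with one shared
  random correlation matrix, A ← (1−σ)A + σS with σ = 0.1 by default,
  then floored to SPD at 1e-6.  Both classes at a site share S, making
  the site a genuine nuisance covariate.
- **Sampling**: T = 150 i.i.d. zero-mean Gaussian draws per subject
  (no temporal autocorrelation — sufficient for covariance-based
  connectivity, and a stated non-goal to model hemodynamics or motion).
  A single root SeedSequence spawns per-site and per-subject streams,
  so cohorts are reproducible and order-independent.

What the generator does *not* emulate: temporal autocorrelation,
heteroscedastic noise, site-varying sample sizes, scanner-specific
frequency content, unbalanced diagnoses.  Passing tests therefore show
the pipeline recovers covariance-level class structure across additive
site nuisance — not that it would attain comparable accuracy on real
acquisition data.

## Numerical choices

- Karcher mean fixed point stops when the mean-log Frobenius norm drops
  below 1e-8 (at most 200 iterations); symmetric eigendecompositions
  back all matrix functions.  Cross-checked against nilearn's geometric
  mean in the test suite.
- SGNS uses summed word2vec-style updates (lr 0.025, linear decay)
  accumulated densely through one-hot matmuls; the batch is capped at
  16 × vocabulary so each row's summed step stays bounded — without the
  cap, small vocabularies (layer graphs, toy fixtures) diverge.
- DTW on empty degree sequences: a single empty sequence costs the
  nonempty one aligned against degree 1; two empty sequences cost 0.
  Struc2vec layer depth K is capped at the graph diameter.
- Rasterization cell values default to **node strength** (the node's
  weighted degree) rather than node count.  Count images discard all
  edge-weight information; measured on the synthetic conditions, they
  carry essentially no class signal (a linear probe on held-out sites
  performs at chance), because the class effect lives entirely in edge
  weights.  Strength deposits retain first-order weight information
  while keeping the construction otherwise identical; the count
  convention remains available (`cell_value="count"`) and is what the
  mass-conservation checks use (each channel then sums to N).
- Dropout is inverted (scaling at train time), so inference is
  deterministic.  Tie-breaks in `predict` go to the control class.

## Benchmark problem sizes

The reference experiments (`neurowalk.benchmarks`, also exercised by
`scripts/acceptance.py`) run scenario s3 end to end:

- *Effect recovery*: 4 sites × 25 + 25 subjects (n = 200), δ = 0.4,
  σ_site = 0.1; embeddings with 10 walks × 40 nodes per node, window
  10, 3 SGNS epochs; CNN for 100 epochs without early stopping.  LOSO
  mean accuracy on these conditions is ≈ 0.85–0.90 for the fixed
  benchmark seeds; it varies by roughly ±0.1 across cohort draws
  because the strength summary's class separation itself fluctuates
  with the sampled site perturbations.
- *Null calibration*: ten 4-site cohorts of 40 subjects with δ = 0,
  reduced walk budget (5 × 20, window 5); pooled LOSO accuracy over the
  400 predictions sits inside the binomial 95% interval around 0.5.

The walk and epoch budgets are deliberate desk-scale reductions of the
package defaults (10 × 80 walks, window 10, 5 SGNS epochs); larger
budgets converge the embeddings further but change the benchmark
picture only marginally.

Early stopping on a validation split is supported
(`validation_fraction` > 0, patience on validation loss) but the
benchmarks train for a fixed epoch count: with ~150 training images a
30-image validation split is noisy enough to stop training at
essentially random points, which hurt held-out accuracy in every
configuration tried.

## Known limitations

- Per-subject SGNS runs share an initialization seed, which keeps
  embeddings comparable across subjects, but the embedding space is
  still only approximately aligned; downstream images inherit this
  variance.
- The walk → skip-gram → PCA → histogram chain is strongly lossy: a
  linear model on raw connectivity separates the synthetic classes
  perfectly while the image pipeline does not.  This mirrors the
  method's design (the images are a compact, translation-tolerant
  summary), not an implementation defect.
- AWE with the default η = 10,000 walks per node is the slowest
  embedding; tests and benchmarks use smaller η where only shape or
  composition is under test.
- The struc2vec implementation concatenates per-layer corpora rather
  than linking layers by cross-layer jump probabilities, and omits the
  original approximations (OPT1–3); at N = 39 neither is a practical
  limitation.
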