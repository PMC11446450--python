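# Methods

## Problem and design

Two-dimensional embeddings of single-cell expression data (t-SNE, UMAP) are
routinely criticized for distorting high-dimensional distances. The criticism
is often backed by *distance-preservation* metrics, on which a linear 2D PCA
projection — or even an embedding deliberately forced into an arbitrary shape —
scores as well as or better than the neighbor-embedding methods. This package
operationalizes the counter-argument: embedding quality is multi-dimensional,
and metrics of *neighborhood* and *class* preservation dissociate sharply from
distance preservation. On data with known ground-truth classes, t-SNE and UMAP
recover the classes almost perfectly while 2D PCA and a shape-constrained
autoencoder do not, even though PCA wins on centroid-distance correlation.

The benchmark therefore has four parts: a count simulator with known classes,
four embedders, six metrics, and an orchestrator that runs
embedders × seeds → metrics → aggregates.

## Synthetic data

`simulate_nb_counts` draws cells × genes counts from a negative binomial
distribution in the mean/size parameterization: a count with mean μ and size
(dispersion) θ has variance μ + μ²/θ. This is the standard overdispersed noise
model for UMI counts; we state the parameterization explicitly because the
NB's (r, p) convention is a recurrent source of bugs.

* Per-gene baseline means are log-normal: `exp(N(baseline_log_mean,
  baseline_log_sd))` with defaults `ln 0.5` and `1.0`, giving the long right
  tail of mean expression typical of droplet data (most genes well below one
  count per cell, a few highly expressed).
* Each class up-regulates a *disjoint* block of marker genes
  (`marker_fraction` = 5% of genes per class, default 50 of 1000) by
  `marker_log2_fc` = 2 (a 4× mean shift). Disjointness makes the ground truth
  identifiable by construction.
* Defaults: 10 classes × 500 cells × 1000 genes, θ = 10, seed 0. These were
  chosen so that classes are cleanly separable in the high-dimensional space
  (HD kNN accuracy ≈ 1) while overlapping heavily in any 2D linear projection —
  ten clusters cannot be linearly separated in two dimensions. This is the
  regime in which the metric dissociation is visible and the regime real
  atlas-scale data sits in.

What the generator does **not** emulate: library-size variation between cells,
batch effects, doublets, trajectory (continuous) structure, and gene–gene
correlation beyond the class structure. Passing benchmarks on this simulation
therefore demonstrate the metric dissociation under clean cluster structure;
they do not certify behavior on continuous or batch-confounded manifolds.

`preprocess` scales each cell to the median total count (a per-cell depth
normalization), applies natural `log1p`, and optionally projects to
`pca_dim` = 50 components. Cells with zero counts are an error (named in the
message) rather than silently dropped. The "high-dimensional gene space" used
as the metric reference is the normalized log matrix *before* PCA;
`hd_space="pca"` switches it.

## Embedders

* **PCA** — closed-form top-2 eigendecomposition of the covariance (or Gram
  matrix when cells < genes). Axis signs are fixed by orienting each
  component so its largest-magnitude loading is positive, making the output
  reproducible across linear-algebra backends. Rank < 2 input is an error.
* **t-SNE** — `sklearn.manifold.TSNE`, library defaults, `n_jobs=1`,
  caller-supplied `random_state`. Note scikit-learn's default PCA
  initialization makes the optimization deterministic given the input, so
  the five "runs" coincide; the run protocol still executes them so that
  non-default (random-init) configurations produce honest error bars.
* **UMAP** — `umap-learn`, library defaults, seeded (which forces
  single-threaded, reproducible mode).
* **Shape-constrained autoencoder** — the adversarial baseline. A tanh MLP
  (widths d→128→32→2→32→128→d, linear bottleneck and output) trained with
  mini-batch Adam on
  `MSE(x, x̂) + shape_weight · Chamfer²(codes, shape points)`,
  where the squared symmetric Chamfer term is the mean squared distance from
  each 2D code to its nearest contour point *plus* the mean squared distance
  from each contour point to its nearest code. The first term pulls every
  cell onto the contour; the second forces the codes to cover the whole
  contour, so the elephant is filled rather than collapsed onto one arc.
  Features are standardized before training, making the reconstruction term
  scale-free and `shape_weight` (default 20) transferable across datasets.
  The learning rate (default 3·10⁻³) follows a cosine decay to 5% of its
  initial value; without the decay, late-training Adam jitter leaves the
  codes hovering a few percent of the shape diameter off the contour.
  Training is fully seeded (weight init and batch order); convergence is
  declared when the mean nearest-contour distance is ≤ 5% of the shape
  diameter, and failure to converge is recorded as a warning in the
  embedding's metadata, not a hard error — a non-adhering shape embedding is
  still a valid (if weaker) adversary.

Target shapes: unit circle, two interleaved half-circle "moons", and a
truncated-Fourier elephant outline (the classic four-term contour, scaled to
unit size; fixture version v1). All are ordered contour samples; `ShapeSpec`
caches the maximum pairwise distance as the shape diameter.

## Metrics

All neighbor computations are exact brute-force Euclidean; ties are broken by
ascending point index via a stable sort, so results are reproducible to the
bit. Small problems use exact difference-based distances; large blocks use
the BLAS Gram identity (the precision difference is ~10⁻¹², far below any
metric's resolution).

* **kNN accuracy** (k = 10): leave-one-out classification — each point takes
  the majority label of its k nearest neighbors; vote ties fall back to the
  single nearest neighbor's label. The mean same-label-neighbor fraction is
  available as `mode="fraction"`; the classification variant is the default
  because it is the convention of the embedding-benchmark literature.
* **kNN recall** (k = 10): mean fraction of a point's k HD neighbors that
  reappear among its k 2D neighbors. Chance level is k/(n−1).
* **Silhouette**: mean of (b−a)/max(a,b) with a the mean within-class and b
  the smallest mean other-class distance; singleton-class points score 0; a
  single class overall is an error.
* **AMI**: (MI − E[MI]) / (mean(Hₐ, H_b) − E[MI]) with the *exact*
  permutation-model E[MI], computed per contingency cell as a hypergeometric
  expectation in log-space. A zero denominator (e.g. an all-in-one-cluster
  partition) returns 0 by convention.
* **ami_max**: HDBSCAN (scikit-learn implementation) is run on the 2D
  coordinates over a grid (min_cluster_size ∈ {5, 10, 25, 50, 100, 250} ×
  min_samples ∈ {5, 10} by default) and the maximum AMI against the true
  classes is reported; per-grid-entry values are retained. Noise points form
  one dedicated extra cluster by default — an embedding HDBSCAN cannot
  cluster is thereby penalized; `noise_mode="exclude"` drops them instead.
  An all-noise clustering contributes AMI 0.
* **Inter-/intra-class correlation**: Pearson (Spearman via flag) between the
  C(C−1)/2 pairwise class-centroid distances, and between the C per-class
  variances (mean squared distance of members to their class centroid),
  each computed in HD and in 2D. Fewer than 3 classes is an error; a
  zero-variance distance vector yields NaN ("undefined") rather than a
  fabricated value.
* **HD baselines**: kNN accuracy and silhouette evaluated with the HD matrix
  in place of 2D coordinates (the dotted lines in the report figure).

## Run protocol and aggregation

The benchmark runs every requested embedder for every seed in the seed list
(default {0..4}); PCA, being fully deterministic, runs once and its value is
reused across the aggregate. Aggregates are (mean, min, max) over runs; error
bars in the rendered figure span min–max. Every stage logs a structured line
(stage name, wall time, input fingerprint) to stderr; all artifacts (counts as
MatrixMarket + TSV companions, one TSV per embedding, long-format report TSV,
provenance JSON with a config hash) are written incrementally so a failed run
preserves partial outputs. Reports contain no timestamps, so identical
configurations produce byte-identical files.

## Numerical choices and degenerate inputs

* kNN distance ties → ascending index; accuracy vote ties → nearest
  neighbor's label; both documented above and enforced by tests.
* AMI denominator |·| < 10⁻¹⁵ → 0; silhouette denominator 0 → s = 0.
* PCA rank deficiency (second singular value at machine-precision scale) is
  an error, not a silent 1D embedding.
* The shape trainer drops the trailing partial mini-batch of each epoch;
  batch composition is reshuffled per epoch from the seeded generator.

## Problem sizes

The default study (10 × 500 × 1000, five seeds, all four embedders, full
metric suite) completes in roughly five minutes on one CPU core; unit tests
use smaller instances (≤ 3 classes, ≤ a few hundred cells) except for the
statistical calibration tests, which need ~10⁵ NB draws or n = 1000 random
embeddings to resolve their expectations.

## Known limitations

* kNN recall of t-SNE/UMAP on the default simulation is a few percent —
  above chance and above PCA, but small in absolute terms; with ten
  interchangeable isotropic classes most within-class neighbor identity is
  genuinely unrecoverable in 2D.
* The shape embedder is a behavioral stand-in for arbitrary-shape
  autoencoders: it reproduces the observable phenotype (data forced onto a
  prescribed contour with above-chance distance-metric scores) without
  claiming architectural fidelity to any published implementation.
* Real-data loaders (MTX/TSV) are provided and tested, but no published
  dataset ships with the package; NB parameter estimation from real data is
  left as a user hook.
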