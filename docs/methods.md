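# Methods

## The model

scPMP (single-cell path-metric profiling) clusters and embeds a
cell-by-feature matrix `X ∈ R^{n×d}` using the family of p-power-weighted
path metrics

    ℓ_p(a, b) = inf over point sequences a = x_0, …, x_s = b of
                ( Σ_i ‖x_{i+1} − x_i‖₂^p )^{1/p},        p ≥ 1,

with paths restricted to a K₂-nearest-neighbor graph.  At `p = 1` on a
complete graph this is Euclidean distance, and on a KNN graph it
approximates geodesic distance along the sampled structure; as `p → ∞`
it converges to the bottleneck (minimax single-edge) distance, which
depends only on density connectivity.  Intermediate `p` interpolates:
many short hops through densely sampled regions are cheaper than one
long hop of the same total length, so the metric contracts
density-connected structure while still growing with geometric
separation.  That balance is what makes it effective for data whose
clusters are simultaneously elongated (bad for k-means) and bridged or
poorly density-separated (bad for DBSCAN-style methods) — the regime
typical of scRNA-seq from developmental processes.  `p = 2` is the
default; data with strongly elongated clusters (high elongation score,
below) tend to prefer larger `p`.

## Pipeline

1. **Denoising** (`preprocess.local_average`): each row is replaced by
   the mean of its `K1` Euclidean nearest neighbors, the point itself
   included (so `K1 = 1` is the identity).  Default `K1 = 12`.
2. **Path metrics** (`path_metrics`): build the symmetrized K₂NN graph
   (edge iff either endpoint ranks the other among its K₂ nearest;
   weight `‖x_i − x_j‖₂^p`), run Dijkstra from every source, and take
   the `1/p` power of the summed weights.  Default `K2 = min(n, 500)`.
   All-pairs cost is `O(K n²)` up to log factors.
3. **Classical MDS** (`mds`): `B = −½ J D^{(2)} J`, eigendecomposition,
   embedding columns `√λ_i · v_i`.  The embedding dimension `r` is the
   index maximizing the eigenratio `λ_i/λ_{i+1}` over `r_min ≤ i ≤
   r_max` with the floor `λ_i/λ_1 ≥ τ` (defaults 3, 39, 0.01).
4. **Clustering** (`clustering.constrained_kmeans`): k-means with 20
   k-means++ replicates; while any cluster is smaller than `min_size`,
   k is increased by one, refit, and each tiny cluster merged into the
   non-tiny cluster with the nearest centroid (retry cap 10).  Default
   `min_size = ⌈√n / 2⌉`; a plain unconstrained mode exists for data
   with genuinely small clusters.  When `k` is unknown,
   `select_k_silhouette` picks the candidate maximizing mean silhouette
   width in the embedding.

### Landmark fast path

For large `n`, `landmark_path_distances` computes path distances only
from `q` uniformly drawn (seeded) landmarks on the same full-data graph,
and `landmark_embed` runs classical MDS on the `q × q` landmark block,
placing every point j from its squared landmark distances δ_j via
`y_j = −½ Λ^{−1/2} Vᵀ (δ_j − δ̄)`.  For a landmark this reproduces its
block-MDS coordinate exactly, so `q = n` recovers full MDS; cost drops
to `O(qn log n)` for distances and `O(q³)` for the spectrum.

## Evaluation statistics

- **ARI** — chance-corrected pair-counting agreement with ground truth
  (scikit-learn implementation behind the module surface).
- **ECP / ECA** — mean Shannon entropy (natural log) of the true-label
  distribution within each predicted cluster (purity), resp. of the
  predicted labels within each true class (accuracy); 0 for a perfect
  partition.  The mean is unweighted by default; a cluster-size-weighted
  variant is available (`weighted=True`) since both conventions appear
  in the literature.
- **Geometric perturbation** `π(X, Y, ℓ) = min_c ‖D_{μ,X} − c·D_{μ,Y}‖²_F /
  ‖D_{μ,X}‖²_F` with the closed-form optimum `c* = ⟨D_{μ,X}, D_{μ,Y}⟩ /
  ‖D_{μ,Y}‖²_F`, where `D_{μ,·}(i, j)` is the distance between the
  ground-truth cluster means of the clusters containing points i and j.
  Implemented in the equivalent k × k form with cluster-pair count
  weights `n_a n_b`, which avoids the n × n matrix.  π is invariant to
  rotation, translation and uniform scaling of the embedding, and is
  undefined (raises) when all embedding cluster means coincide, e.g.
  concentric configurations.
- **Elongation score** `G1 = n/((n−1)(n−2)) Σ ((d_i − d̄)/s)³`, the
  bias-corrected sample skewness of the distances to the k-th nearest
  neighbor at `k = round(10 ln n)` (sample standard deviation, n−1).
  Natural log is used; the convention is configurable through `k_nn`.

## Synthetic benchmarks

The generators emulate four separability regimes at their standard
sizes; all shape parameters are named `GeneratorSpec.extra` entries.

- **balls** (n=1200, d=2, k=3): uniform disks of radius 1 with centers
  an equilateral triangle of side 1.95.  The side length was set so the
  overlap reproduces the reference clustering accuracies (plain k-means
  ≈ 0.96, path-metric pipeline ≈ 0.92); geometric but not density
  separation.
- **ewb** (n=620, d=2, k=3): three Gaussians elongated 3.0 vs 0.35,
  centers 4 apart, plus a 20-point bridge joining two of them.  Bridge
  points are evenly spaced with sub-spacing jitter so the largest gap
  along the bridge stays below the typical intra-cluster spacing —
  dense enough to defeat pure density clustering while the p = 2
  metric still pays a premium for crossing it.  Bridge points take the
  label of the nearer bridged cluster.
- **swiss_roll** (n=1275, d=3, k=3): `(t cos t, y, t sin t)` with t in
  three bands of `[1.5π, 4.5π]` separated by gaps of 1.5 in t, y
  uniform on [0, 21], isotropic Gaussian noise σ = 0.75.  The gap width
  keeps the bands density-separated under that noise.
- **so3** (n=3000, d=1000, k=3): conjugation orbits `{V D_i Vᵀ : V ∈
  SO(3)}` flattened to R⁹ (an isometry), embedded in the first 9 of
  1000 coordinates, uniform noise of sd 0.0075 everywhere.  The three
  spectra D_i sit on the circle of eigenvalue triples with common trace
  and Frobenius norm (angles 5°, 15°, 25° — the permutation symmetry of
  eigenvalues folds the circle into a 30° fundamental domain, so
  angular separation alone is weak) plus per-cluster trace offsets
  (−0.8, 0, +0.8).  Orbit means can differ only along the trace
  direction; the offsets are sized so full-dimensional distances
  separate the orbits while their between-cluster variance stays far
  below the orbit spread, leaving 2-D PCA with no visible separation.
- **sim_beta** (n=473, d=2279, k=3): log-normal per-gene base means
  (synthetic stand-ins for real beta-cell means, log-sd 1.5), 10%
  marker genes split across clusters and scaled ×3, per-cell efficiency
  ~ Gamma(shape 10, rate 100) (mean 0.1), Poisson counts.  Defaults
  give ≈80% zeros — droplet-like sparsity.

What the generators do *not* emulate: real expression data's gene-gene
correlation, batch effects, heavy-tailed over-dispersion beyond
Poisson-Gamma, or upstream normalization/imputation choices.  Passing
benchmarks therefore demonstrates the mechanics of the method under
controlled separability regimes, not performance on any particular real
data set.

## Numerical choices

- Pairwise Euclidean distances: exact (`scipy.spatial.distance.cdist`)
  below ~2·10⁹ multiply-adds, BLAS Gram-identity (clipped at 0) above;
  neighbor ties broken by lowest index via stable argsort, making every
  stage deterministic.
- Duplicate points keep an explicit (denormal-magnitude) zero-weight
  edge so they remain path-connected at distance ≈ 0.
- Dijkstra output is used as computed per source (no re-symmetrization),
  so landmark rows equal full-matrix rows exactly; asymmetry is at
  float-rounding level.
- Eigenvector signs are fixed by making each vector's largest-magnitude
  entry positive.  Negative eigenvalues (path distances need not be
  Euclidean-embeddable) are clipped to zero and never embedded; if r
  exceeds the count of meaningfully positive eigenvalues it is reduced
  with a warning.
- The eigenratio selector treats a gap onto a nonpositive eigenvalue as
  infinite, breaks ties toward the smallest admissible index, and falls
  back to `r_min` (with a warning) when no index passes the τ floor.
- The printed construction `Y = (λ₁v₁, …)` differs from the classical
  `√λ` scaling that reproduces distances; the default is
  `sqrt_eigenvalue` (distance-faithful, and the axis-scale-sensitive
  perturbation statistic depends on it), with an `eigenvalue` mode kept
  for literal reproducibility.
- Disconnected KNN graphs yield explicit infinite distances and
  `connected=False`; MDS refuses infinite input with an error naming the
  cause rather than silently substituting a sentinel.

## Problem sizes in the shipped benchmarks

The acceptance script and benchmark tests run all four toy sets at
their standard sizes over 10 seeds.  Balls, EWB and the Swiss roll use
full all-pairs mode; the SO(3) set (n=3000, d=1000) runs through the
landmark path with q=600 — the same scalable route recommended for any
data set of thousands of cells — which leaves its accuracy at ARI 1
while keeping each run tens of seconds.  Geometric-perturbation checks
average 3 seeds.

## Known limitations

- All-pairs mode stores an n × n dense distance matrix; beyond ~10⁴
  cells the landmark path is mandatory in practice.
- The minimum-size rule can overshoot (more than k adequately sized
  clusters while growing k); the implementation then stops and returns
  the labels with a warning rather than merging well-sized clusters.
- π is meaningless when cluster means nearly coincide by symmetry.
- The method consumes already-normalized matrices; no library-size
  normalization, transformation, or gene selection is performed.
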