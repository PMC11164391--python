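# scpmp — path-metric embedding and clustering for single-cell data

`scpmp` implements single-cell path-metric profiling: a
density-sensitive, geometry-preserving embedding and clustering method
for cell-by-feature matrices (typically normalized scRNA-seq), together
with its evaluation statistics and seeded synthetic benchmark
generators.

Clustering methods face a tension between *geometry* (k-means wants
convex, well-separated clusters) and *density* (DBSCAN-style methods
follow high-density regions wherever they lead).  scRNA-seq data is
hard on both counts: differentiation trajectories produce elongated
clusters, and transition states produce bridges of cells between them.
The p-power-weighted path metric interpolates between the two views:

    ℓ_p(a, b) = inf over paths a = x_0, …, x_s = b of
                ( Σ_i ‖x_{i+1} − x_i‖₂^p )^{1/p},   p ≥ 1,

with paths restricted to a K₂-nearest-neighbor graph.  `p = 1` is
Euclidean/geodesic distance, `p → ∞` the bottleneck distance; at the
default `p = 2`, many short hops through dense data are cheaper than
one long hop, so density-connected structure contracts while
geometric separation is preserved.  The pipeline denoises by local
averaging (K₁ = 12), computes all-pairs (or landmark) path distances
with Dijkstra on the K₂NN graph (K₂ = min(n, 500)), embeds them with
classical MDS — choosing the dimension at the largest eigenratio
λ_i/λ_{i+1} within [3, 39], subject to λ_i/λ₁ ≥ 0.01 — and clusters
with size-constrained k-means (20 replicates, minimum cluster size
⌈√n/2⌉).  Quality is assessed with ARI/ECP/ECA against ground truth,
geometric fidelity with the scale-optimal cluster-mean discrepancy π,
and data elongation with the skewness statistic G1 of k-NN distances.
See `docs/methods.md` for the full account.

## Worked example

```python
from scpmp import RunConfig, adjusted_rand_index, run_pipeline, synthetic

# three elongated Gaussians, two of them joined by a bridge of points
X, truth = synthetic.generate(synthetic.default_spec("ewb", seed=0))
result = run_pipeline(X, RunConfig(p=2.0, k=3, seed=0))
print(result.embedding.r, adjusted_rand_index(truth, result.labels))
```

prints

```
5 0.9901843275623957
```

— the embedding dimension selected by the eigenratio rule (5) and the
adjusted Rand index against the planted labels (0.99, near-perfect
recovery).  On the same data, plain k-means scores 0.48: the elongated
clusters defeat its convex cluster model, while the path metric
contracts each cluster before clustering.  The scripts in `examples/`
walk through one capability each (path-metric behavior across p,
end-to-end benchmarking, landmark scaling, geometric fidelity, count
simulation) and print what the numbers mean.

A thin CLI mirrors the library for shell use:

```bash
scpmp simulate ewb --out-dir sim/ --seed 0
scpmp cluster sim/matrix.csv --out labels.csv -k 3 --seed 0
scpmp evaluate sim/labels.csv labels.csv
```

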