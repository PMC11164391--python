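"""End-to-end clustering of a synthetic benchmark.

Generates the elongated-Gaussians-with-bridge benchmark (three elongated
clusters, two of them joined by a thin bridge of points — the regime
where both plain k-means and pure density clustering fail), runs the
full path-metric pipeline at p = 2, and scores the result against the
planted labels.
"""

from sklearn.cluster import KMeans

from scpmp import RunConfig, adjusted_rand_index, entropy_metrics, run_pipeline, synthetic

spec = synthetic.default_spec("ewb", seed=0)
X, truth = synthetic.generate(spec)
print(f"generated {spec.name}: n={X.n} cells, d={X.d} features, k={truth.k} clusters")

result = run_pipeline(X, RunConfig(p=2.0, k=3, seed=0))
ari = adjusted_rand_index(truth, result.labels)
ecp, eca = entropy_metrics(truth, result.labels)
print(f"path-metric pipeline: r={result.embedding.r}, ARI={ari:.3f}, "
      f"ECP={ecp:.3f}, ECA={eca:.3f}")

km = KMeans(n_clusters=3, n_init=20, random_state=0).fit_predict(X.values)
print(f"plain k-means baseline: ARI={adjusted_rand_index(truth.labels, km + 1):.3f}")

print()
print("ARI of 1 means perfect recovery of the planted clusters; ECP/ECA of 0\n"
      "mean every estimated cluster is pure and every true class intact.\n"
      "k-means fails here because the elongated clusters defeat its convex,\n"
      "isotropic cluster model; the path metric contracts each elongated\n"
      "cluster before clustering.")
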