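"""Landmark approximation for large data sets.

Path distances from q landmark points (instead of all n sources) cut
the shortest-path cost from O(n^2) to O(qn) and the MDS
eigendecomposition from n x n to q x q, at no loss in clustering
quality when q is a reasonable fraction of n.  Here: three noisy bands
of a Swiss roll, full mode vs 80 landmarks.
"""

import time

from scpmp import RunConfig, adjusted_rand_index, run_pipeline, synthetic

spec = synthetic.default_spec("swiss_roll", seed=1, n=600)
X, truth = synthetic.generate(spec)
print(f"Swiss roll sample: n={X.n}, 3 angular bands, noise sd {spec.noise_sd}")

for label, landmarks in (("full (all-pairs)", None), ("landmark (q=80)", 80)):
    t0 = time.perf_counter()
    res = run_pipeline(X, RunConfig(p=2.0, k=3, seed=1, landmarks=landmarks))
    ari = adjusted_rand_index(truth, res.labels)
    print(f"{label:18s} ARI={ari:.3f}  r={res.embedding.r}  "
          f"time={time.perf_counter() - t0:.1f}s")

print()
print("Both modes recover the bands; the landmark run only computes path\n"
      "distances from 80 seeded landmark points and places the remaining\n"
      "cells by triangulation against the landmark embedding.")
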