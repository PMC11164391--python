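"""End-to-end scPMP pipeline.

Denoise by local averaging, compute p-power path metrics on the K2NN
graph (optionally from landmarks only), embed with classical MDS at an
automatically selected dimension, and cluster with size-constrained
k-means (or pick k by the silhouette criterion).  Every stage is seeded
or deterministic, so a run is reproducible from its RunConfig alone.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

from . import clustering as _clustering
from . import mds as _mds
from . import path_metrics as _pm
from .datatypes import ClusterLabels, DataMatrix, Embedding, ParameterError, RunConfig
from .preprocess import local_average

__all__ = ["run_pipeline", "PipelineResult"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    embedding: Embedding
    labels: ClusterLabels
    report: dict = field(default_factory=dict)


def run_pipeline(X: DataMatrix, config: RunConfig | None = None) -> PipelineResult:
    """Run denoise -> path metrics -> MDS -> constrained k-means.

    ``config.landmarks`` switches the path-metric and MDS stages to the
    landmark approximation; ``config.k == "auto"`` selects k by maximal
    silhouette over ``config.k_candidates``.  The report records the
    resolved parameters, selected dimension, spectrum head, stage
    runtimes and warnings.
    """
    config = config or RunConfig()
    n = X.n
    K2 = config.resolved_K2(n)
    report: dict = {
        "n": n,
        "d": X.d,
        "p": config.p,
        "K1": config.K1,
        "K2": K2,
        "landmarks": config.landmarks,
        "seed": config.seed,
        "timings": {},
        "warnings": [],
    }

    def _stage(name):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()
                return self

            def __exit__(self, *exc):
                report["timings"][name] = round(time.perf_counter() - self.t0, 4)
                logger.info("stage %s: %.2fs", name, report["timings"][name])
                return False

        return _T()

    try:
        with _stage("denoise"):
            Xd = local_average(X, config.K1) if config.denoise else X
        with _stage("path_metrics"):
            if config.landmarks is not None:
                D = _pm.landmark_path_distances(
                    Xd, q=config.landmarks, K2=K2, p=config.p, seed=config.seed
                )
            else:
                G = _pm.build_knn_graph(Xd, K2=K2, p=config.p)
                D = _pm.path_distances(G)
            if not D.connected:
                report["warnings"].append("KNN graph disconnected")
        with _stage("mds"):
            r_max = min(config.r_max, n - 1)
            if D.is_landmark:
                emb = _mds.landmark_embed(
                    D, r=None, r_min=config.r_min, r_max=r_max, tau=config.tau,
                    scaling_mode=config.scaling_mode,
                )
            else:
                emb = _mds.embed_distances(
                    D, r=None, r_min=config.r_min, r_max=r_max, tau=config.tau,
                    scaling_mode=config.scaling_mode,
                )
            report["r"] = emb.r
            report["spectrum_head"] = [float(v) for v in emb.eigenvalues[:10]]
        with _stage("cluster"):
            min_size = config.resolved_min_size(n)
            if config.k == "auto":
                k = _clustering.select_k_silhouette(
                    emb, config.k_candidates, seed=config.seed,
                    replicates=config.replicates, min_size=min_size or None,
                    constrained=config.constrained,
                )
                report["k_auto"] = k
            else:
                k = int(config.k)
            labels = _clustering.constrained_kmeans(
                emb, k, replicates=config.replicates,
                min_size=min_size if config.constrained else None,
                seed=config.seed, constrained=config.constrained,
            )
            report["k"] = labels.k
            report["cluster_sizes"] = [int(s) for s in labels.sizes()]
    except (ParameterError, ValueError) as exc:
        raise type(exc)(f"[pipeline] {exc}") from exc
    return PipelineResult(embedding=emb, labels=labels, report=report)
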