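"""Seeded generators for the benchmark data sets.

Four toy manifolds exercise distinct cluster-separability regimes —
overlapping uniform balls (geometric but not density separation),
elongated Gaussians joined by a bridge (neither separation is clean),
bands of a noisy Swiss roll and SO(3) conjugation orbits in high
dimension (intertwined geometry, good density separation) — plus a
simulated beta-cell scRNA-seq count matrix with marker-gene clusters and
Poisson capture noise.  Every shape parameter is a named entry of
``GeneratorSpec.extra`` with documented defaults, so a benchmark draw is
fully described by (name, n, k, noise_sd, seed, extra).
"""

from __future__ import annotations

import warnings

import numpy as np

from .datatypes import ClusterLabels, DataMatrix, GeneratorSpec, ParameterError

__all__ = [
    "default_spec",
    "generate",
    "make_balls",
    "make_ewb",
    "make_swiss_roll",
    "make_so3",
    "make_sim_beta",
    "GENERATORS",
]

_TWO_PI = 2.0 * np.pi

#: per-generator standard sizes and shape defaults
_DEFAULTS: dict[str, dict] = {
    "balls": dict(
        n=1200, k=3, noise_sd=0.0,
        extra=dict(radius=1.0, center_distance=1.95),
    ),
    "ewb": dict(
        n=620, k=3, noise_sd=0.0,
        extra=dict(
            center_spacing=4.0,      # x-distance between adjacent centers
            sd_short=0.35,           # cross-section sd of each Gaussian
            sd_long=3.0,             # elongated-axis sd (>= 5:1 ratio)
            n_bridge=20,
            bridge_pair=(1, 2),      # clusters joined by the bridge
            bridge_margin=0.5,       # offset of bridge ends from the centers
        ),
    ),
    "swiss_roll": dict(
        n=1275, k=3, noise_sd=0.75,
        extra=dict(
            t_min=1.5 * np.pi, t_max=4.5 * np.pi,
            band_gap=1.5,            # gap in roll parameter between bands
            height=21.0,
        ),
    ),
    "so3": dict(
        n=3000, k=3, noise_sd=0.0075,
        extra=dict(
            d=1000,
            # spectra of the D_i: points on the circle of eigenvalue
            # triples with fixed trace and Frobenius norm, plus small
            # per-cluster trace offsets; the offsets separate the orbits
            # in full dimension while staying invisible to 2-D PCA
            # (their between-cluster variance is below the orbit spread)
            spectrum_center=2.0,
            spectrum_radius=np.sqrt(8.0),
            spectrum_angles_deg=(5.0, 15.0, 25.0),
            trace_offsets=(-0.8, 0.0, 0.8),
        ),
    ),
    "sim_beta": dict(
        n=473, k=3, noise_sd=0.0,
        extra=dict(
            d=2279,
            marker_fraction=0.10,
            scale_up=3.0,
            efficiency_shape=10.0,
            efficiency_rate=100.0,
            base_log_mean=0.0,
            base_log_sd=1.5,
        ),
    ),
}


def default_spec(name: str, seed: int = 0, **overrides) -> GeneratorSpec:
    """The documented default GeneratorSpec for one benchmark.

    ``overrides`` update the top-level fields (n, k, noise_sd) or, via an
    ``extra`` dict, individual shape parameters.
    """
    if name not in _DEFAULTS:
        raise ParameterError(f"unknown generator {name!r}; choose from {sorted(_DEFAULTS)}")
    base = _DEFAULTS[name]
    extra = dict(base["extra"])
    extra.update(overrides.pop("extra", {}))
    fields = dict(n=base["n"], k=base["k"], noise_sd=base["noise_sd"])
    fields.update(overrides)
    return GeneratorSpec(name=name, seed=seed, extra=extra, **fields)


def _split_sizes(n: int, k: int) -> np.ndarray:
    """Split n into k parts; the remainder is assigned round-robin."""
    sizes = np.full(k, n // k)
    sizes[: n % k] += 1
    return sizes


def _labels(sizes: np.ndarray) -> np.ndarray:
    return np.repeat(np.arange(1, len(sizes) + 1), sizes)


def make_balls(spec: GeneratorSpec | None = None):
    """Uniform samples from three pairwise-overlapping disks in R^2."""
    spec = spec or default_spec("balls")
    rng = np.random.default_rng(spec.seed)
    radius = spec.extra["radius"]
    c = spec.extra["center_distance"]
    centers = np.array([[0.0, 0.0], [c, 0.0], [c / 2.0, c * np.sqrt(3) / 2.0]])
    if spec.extra.get("overlap_required") and c >= 2 * radius:
        raise ParameterError(
            f"disks at center distance {c} with radius {radius} do not overlap"
        )
    sizes = _split_sizes(spec.n, spec.k)
    pts = []
    for j, m in enumerate(sizes):
        r = radius * np.sqrt(rng.uniform(size=m))
        theta = rng.uniform(0.0, _TWO_PI, size=m)
        pts.append(centers[j % 3] + np.c_[r * np.cos(theta), r * np.sin(theta)])
    X = np.vstack(pts)
    if spec.noise_sd > 0:
        X = X + rng.normal(scale=spec.noise_sd, size=X.shape)
    return DataMatrix(values=X), ClusterLabels(_labels(sizes), k=spec.k, source="ground_truth")


def make_ewb(spec: GeneratorSpec | None = None):
    """Three elongated Gaussians with a uniform bridge joining two of them.

    Gaussian j is centered at (j * center_spacing, 0) with diagonal
    covariance (sd_short^2, sd_long^2), elongated along y.  The bridge is
    a uniform line segment of points along y = 0 between the two bridged
    clusters; bridge points take the label of the nearer bridged center.
    """
    spec = spec or default_spec("ewb")
    rng = np.random.default_rng(spec.seed)
    ex = spec.extra
    a, b = ex["bridge_pair"]
    if a == b:
        raise ParameterError("bridge must join two distinct clusters")
    n_bridge = int(ex["n_bridge"])
    sizes = _split_sizes(spec.n - n_bridge, spec.k)
    spacing, sd = ex["center_spacing"], np.array([ex["sd_short"], ex["sd_long"]])
    centers = np.c_[np.arange(spec.k) * spacing, np.zeros(spec.k)]
    pts = [centers[j] + rng.normal(size=(m, 2)) * sd for j, m in enumerate(sizes)]
    labels = [_labels(sizes)]
    if n_bridge > 0:
        lo = centers[a - 1] + np.array([ex["bridge_margin"], 0.0])
        hi = centers[b - 1] - np.array([ex["bridge_margin"], 0.0])
        if np.linalg.norm(hi - lo) <= 0:
            raise ParameterError("bridge endpoints collapse inside one cluster")
        # evenly spaced with sub-spacing jitter: the max gap along the
        # bridge stays below the intra-cluster spacing, which is what
        # defeats purely density-based clustering
        t = np.linspace(0.0, 1.0, n_bridge)
        if n_bridge > 1:
            t = t + rng.uniform(-0.15, 0.15, size=n_bridge) / (n_bridge - 1)
        bridge = lo + t[:, None] * (hi - lo)
        pts.append(bridge)
        d_a = np.linalg.norm(bridge - centers[a - 1], axis=1)
        d_b = np.linalg.norm(bridge - centers[b - 1], axis=1)
        labels.append(np.where(d_a <= d_b, a, b))
    X = np.vstack(pts)
    if spec.noise_sd > 0:
        X = X + rng.normal(scale=spec.noise_sd, size=X.shape)
    lab = np.concatenate(labels)
    return DataMatrix(values=X), ClusterLabels(lab, k=spec.k, source="ground_truth")


def _band_intervals(t_min: float, t_max: float, k: int, gap: float) -> np.ndarray:
    width = (t_max - t_min - (k - 1) * gap) / k
    if width <= 0:
        raise ParameterError("band gaps exceed the roll parameter range")
    starts = t_min + np.arange(k) * (width + gap)
    return np.c_[starts, starts + width]


def make_swiss_roll(spec: GeneratorSpec | None = None):
    """Uniform samples from three angular bands of a Swiss roll plus noise.

    The roll is (t cos t, y, t sin t) with the roll parameter t uniform
    inside each of k disjoint bands (separated by gaps of ``band_gap`` in
    t) and height y uniform on [0, height]; isotropic Gaussian noise of
    sd ``noise_sd`` is added in R^3.
    """
    spec = spec or default_spec("swiss_roll")
    rng = np.random.default_rng(spec.seed)
    ex = spec.extra
    bands = _band_intervals(ex["t_min"], ex["t_max"], spec.k, ex["band_gap"])
    sizes = _split_sizes(spec.n, spec.k)
    pts = []
    for (lo, hi), m in zip(bands, sizes):
        t = rng.uniform(lo, hi, size=m)
        y = rng.uniform(0.0, ex["height"], size=m)
        pts.append(np.c_[t * np.cos(t), y, t * np.sin(t)])
    X = np.vstack(pts)
    if spec.noise_sd > 0:
        X = X + rng.normal(scale=spec.noise_sd, size=X.shape)
    return DataMatrix(values=X), ClusterLabels(_labels(sizes), k=spec.k, source="ground_truth")


def spectrum_triples(spec: GeneratorSpec) -> np.ndarray:
    """The k eigenvalue triples D_i used by the SO(3) generator.

    The traceless parts of the triples lie on the circle of
    symmetric-matrix spectra with fixed Frobenius norm, parameterized by
    angle inside one fundamental domain of the eigenvalue-permutation
    symmetry (which leaves only 30 degrees of room, so angular
    separation alone is weak).  Small per-cluster trace offsets push the
    orbits apart along the identity direction — the only direction in
    which conjugation-orbit means can differ — sized so that distances
    separate the clusters while 2-D PCA still shows none.
    """
    ex = spec.extra
    c, R = ex["spectrum_center"], ex["spectrum_radius"]
    u1 = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
    u2 = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)
    angles = np.deg2rad(np.asarray(ex["spectrum_angles_deg"], float))
    offsets = np.asarray(ex.get("trace_offsets", np.zeros(len(angles))), float)
    return np.array(
        [
            c + off + R * (np.cos(a) * u1 + np.sin(a) * u2)
            for a, off in zip(angles, offsets)
        ]
    )


def _haar_so3(rng: np.random.Generator, m: int) -> np.ndarray:
    """m rotation matrices, Haar-uniform on SO(3), via sign-fixed QR."""
    A = rng.normal(size=(m, 3, 3))
    Q, R = np.linalg.qr(A)
    # make the QR factorization unique (R diagonal positive) for uniformity
    signs = np.sign(np.einsum("mii->mi", R))
    signs[signs == 0] = 1.0
    Q = Q * signs[:, None, :]
    det = np.linalg.det(Q)
    Q[det < 0, :, 2] *= -1.0  # flip one column to land in SO(3)
    return Q


def make_so3(spec: GeneratorSpec | None = None):
    """Conjugation orbits of fixed-spectrum symmetric matrices in R^1000.

    Cluster i samples V D_i V^T for Haar-uniform V in SO(3), flattens the
    3 x 3 matrix to R^9 (an isometry), embeds it in the first 9 of d
    coordinates, and adds uniform noise of sd ``noise_sd`` in all d
    dimensions.  Orbit means differ only through the matrix trace, and
    the default trace offsets keep that between-cluster variance below
    the orbit spread, so 2-D PCA shows no separation although the
    orbits are density-separated in full dimension.
    """
    spec = spec or default_spec("so3")
    rng = np.random.default_rng(spec.seed)
    d = int(spec.extra["d"])
    if d < 9:
        raise ParameterError("so3 generator needs d >= 9")
    triples = spectrum_triples(spec)
    sizes = _split_sizes(spec.n, spec.k)
    X = np.zeros((spec.n, d))
    row = 0
    for D_i, m in zip(triples, sizes):
        V = _haar_so3(rng, m)
        M = np.einsum("mij,j,mkj->mik", V, D_i, V)  # V diag(D_i) V^T
        X[row : row + m, :9] = M.reshape(m, 9)
        row += m
    if spec.noise_sd > 0:
        half_width = spec.noise_sd * np.sqrt(3.0)  # uniform sd -> half-width
        X = X + rng.uniform(-half_width, half_width, size=X.shape)
    return DataMatrix(values=X), ClusterLabels(_labels(sizes), k=spec.k, source="ground_truth")


def make_sim_beta(spec: GeneratorSpec | None = None):
    """Simulated beta-cell counts: marker genes, capture efficiency, Poisson.

    A per-gene base mean profile (log-normal draws standing in for real
    beta-cell means) is shared by all cells; 10% of genes are marker
    genes, split evenly across the k clusters, and a cluster's marker
    means are multiplied by ``scale_up``.  Each cell's mean vector is
    scaled by an efficiency-loss constant drawn from Gamma(shape 10,
    rate 100) (mean 0.1), and counts are Poisson draws entrywise.
    """
    spec = spec or default_spec("sim_beta")
    rng = np.random.default_rng(spec.seed)
    ex = spec.extra
    d = int(ex["d"])
    if ex["scale_up"] <= 1.0:
        warnings.warn(
            "marker scale_up <= 1 leaves clusters unidentifiable by construction",
            stacklevel=2,
        )
    base = rng.lognormal(mean=ex["base_log_mean"], sigma=ex["base_log_sd"], size=d)
    n_markers = int(round(ex["marker_fraction"] * d))
    markers = rng.choice(d, size=n_markers, replace=False)
    marker_groups = np.array_split(markers, spec.k)
    sizes = _split_sizes(spec.n, spec.k)
    labels = _labels(sizes)
    S = np.tile(base, (spec.n, 1))
    for j, genes in enumerate(marker_groups, start=1):
        S[np.ix_(labels == j, genes)] *= ex["scale_up"]
    efficiency = rng.gamma(shape=ex["efficiency_shape"], scale=1.0 / ex["efficiency_rate"], size=spec.n)
    counts = rng.poisson(S * efficiency[:, None]).astype(float)
    feature_ids = [f"gene{g}" for g in range(d)]
    cell_ids = [f"cell{i}" for i in range(spec.n)]
    return (
        DataMatrix(values=counts, cell_ids=cell_ids, feature_ids=feature_ids),
        ClusterLabels(labels, k=spec.k, source="ground_truth"),
    )


GENERATORS = {
    "balls": make_balls,
    "ewb": make_ewb,
    "swiss_roll": make_swiss_roll,
    "so3": make_so3,
    "sim_beta": make_sim_beta,
}


def generate(spec: GeneratorSpec):
    """Dispatch a GeneratorSpec to its generator."""
    try:
        fn = GENERATORS[spec.name]
    except KeyError:
        raise ParameterError(f"unknown generator {spec.name!r}") from None
    return fn(spec)
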