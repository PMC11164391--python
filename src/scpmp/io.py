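"""Readers and writers for the supported on-disk formats.

Dense matrices travel as CSV/TSV with a header row of feature names and
a first column of cell identifiers; sparse matrices as MatrixMarket
coordinate files with ``features.tsv``/``barcodes.tsv`` sidecars (the
10x convention, genes as on-disk rows).  Labels are two-column CSV
(cell_id, label).  Cells are rows internally everywhere; a transpose
flag adapts gene-by-cell inputs.  Output files get a JSON sidecar with
the tool version and the fully resolved configuration.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io as _spio
import scipy.sparse as _sp
import yaml

from .datatypes import ClusterLabels, DataMatrix, Embedding, RunConfig

__all__ = [
    "read_matrix",
    "write_matrix",
    "read_labels",
    "write_labels",
    "write_embedding",
    "read_config",
    "write_sidecar",
]

#: densify MTX inputs below this many entries
_DENSIFY_LIMIT = 50_000_000


class FormatError(ValueError):
    """Malformed input file."""


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".csv",):
        return "csv"
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix == ".mtx":
        return "mtx"
    raise FormatError(f"cannot infer format from {path.name!r}; pass format=")


def read_matrix(path, format: str | None = None, transpose: bool = False) -> DataMatrix:
    """Read a cell-by-feature matrix from CSV/TSV or MatrixMarket.

    Cells are always rows in memory.  For CSV/TSV the default on-disk
    orientation is cells x features; ``transpose=True`` declares the file
    is feature-by-cell.  For MTX the default orientation is the 10x
    convention features x barcodes (so the matrix is transposed on read);
    ``transpose=True`` declares the file is already barcodes x features.
    MTX sidecars ``features.tsv`` and ``barcodes.tsv`` must sit next to
    the matrix file, one identifier per line.
    """
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        df = pd.read_csv(path, sep=sep, index_col=0)
        bad = df.columns[~df.dtypes.map(lambda t: np.issubdtype(t, np.number))]
        if len(bad):
            line = int(np.flatnonzero(pd.to_numeric(df[bad[0]], errors="coerce").isna())[0]) + 2
            raise FormatError(
                f"{path.name}: non-numeric value in column {bad[0]!r} near line {line}"
            )
        values = df.to_numpy(dtype=float)
        row_ids, col_ids = list(df.index.astype(str)), list(df.columns.astype(str))
        if transpose:
            values, row_ids, col_ids = values.T, col_ids, row_ids
    elif fmt == "mtx":
        try:
            M = _spio.mmread(path)
        except ValueError as exc:
            raise FormatError(f"{path.name}: {exc}") from exc
        if _sp.issparse(M):
            M = M.toarray()  # dense internal representation downstream
        values = np.asarray(M, dtype=float)
        features = _read_id_file(path.parent / "features.tsv")
        barcodes = _read_id_file(path.parent / "barcodes.tsv")
        if not transpose:  # standard features x barcodes orientation
            values = values.T
        row_ids, col_ids = barcodes, features
    else:
        raise FormatError(f"unknown format {fmt!r}")
    if values.shape[0] != len(row_ids) or values.shape[1] != len(col_ids):
        raise FormatError(
            f"{path.name}: matrix shape {values.shape} does not match "
            f"{len(row_ids)} cells x {len(col_ids)} features"
        )
    return DataMatrix(values=values, cell_ids=row_ids, feature_ids=col_ids)


def _read_id_file(path: Path) -> list:
    if not path.exists():
        raise FormatError(f"missing sidecar file {path}")
    ids = [line.split("\t")[0] for line in path.read_text().splitlines() if line]
    if not ids:
        raise FormatError(f"sidecar {path} is empty")
    return ids


def write_matrix(X: DataMatrix, path, format: str | None = None) -> None:
    """Write a DataMatrix as CSV/TSV (cells as rows) or MTX (genes as rows)."""
    path = Path(path)
    fmt = format or _infer_format(path)
    cells = X.cell_ids or [f"cell{i}" for i in range(X.n)]
    feats = X.feature_ids or [f"feature{j}" for j in range(X.d)]
    if fmt in ("csv", "tsv"):
        sep = "," if fmt == "csv" else "\t"
        pd.DataFrame(X.values, index=cells, columns=feats).to_csv(path, sep=sep)
    elif fmt == "mtx":
        _spio.mmwrite(str(path), _sp.coo_matrix(X.values.T))
        (path.parent / "features.tsv").write_text("\n".join(feats) + "\n")
        (path.parent / "barcodes.tsv").write_text("\n".join(cells) + "\n")
    else:
        raise FormatError(f"unknown format {fmt!r}")


def read_labels(path, n: int | None = None) -> ClusterLabels:
    """Read a (cell_id, label) CSV into ground-truth ClusterLabels."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise FormatError(f"{Path(path).name}: expected two columns (cell_id, label)")
    raw = df.iloc[:, 1]
    codes, _ = pd.factorize(raw)
    labels = codes + 1
    if np.issubdtype(raw.dtype, np.integer) and raw.min() >= 1:
        labels = raw.to_numpy()  # keep explicit 1..k integer labels as-is
    if n is not None and len(labels) != n:
        raise FormatError(f"expected {n} labels, found {len(labels)}")
    return ClusterLabels(labels=np.asarray(labels), k=int(np.max(labels)), source="ground_truth")


def write_labels(labels: ClusterLabels, path, cell_ids=None) -> None:
    ids = cell_ids or [f"cell{i}" for i in range(labels.n)]
    pd.DataFrame({"cell_id": ids, "label": labels.labels}).to_csv(path, index=False)


def write_embedding(emb: Embedding, path, cell_ids=None, spectrum_path=None) -> None:
    """Embedding coordinates as CSV; optionally the spectrum as one column."""
    ids = cell_ids or [f"cell{i}" for i in range(emb.n)]
    cols = [f"PM{i + 1}" for i in range(emb.r)]
    pd.DataFrame(emb.coordinates, index=ids, columns=cols).to_csv(path)
    if spectrum_path is not None:
        pd.DataFrame({"eigenvalue": emb.eigenvalues}).to_csv(spectrum_path, index=False)


def read_config(path) -> RunConfig:
    """Load a RunConfig from JSON or YAML; unknown keys are rejected."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise FormatError(f"{path.name}: config must be a mapping")
    valid = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - valid
    if unknown:
        raise FormatError(f"{path.name}: unknown config keys {sorted(unknown)}")
    if "k_candidates" in data:
        data["k_candidates"] = tuple(data["k_candidates"])
    return RunConfig(**data)


def write_sidecar(path, config: RunConfig | None = None, **extras) -> None:
    """JSON sidecar recording tool version and fully resolved parameters."""
    from . import __version__

    payload = {"tool": "scpmp", "version": __version__}
    if config is not None:
        payload["config"] = dataclasses.asdict(config)
    payload.update(extras)
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify) + "\n")


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
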