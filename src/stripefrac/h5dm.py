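"""HDF5 distance-matrix artifacts with O(1) pair access, plus Mantel.

Serializing an N x N distance matrix through text formats dominates
wall-clock time once N reaches the tens of thousands, so distances are
stored in a chunked HDF5 container that supports random access to single
pairs without materializing the matrix:

    /order                      sample ids, in matrix order
    /matrix                     N x N distances, chunked (256 x 256 default)
    /pcoa/eigvals               ) optional embedded ordination
    /pcoa/samples               )
    /pcoa/proportion_explained  )
    attrs: method, alpha, precision, version

The matrix is stored in full (not condensed) so a pair probe touches O(1)
chunks.  The Mantel test compares two such artifacts: Pearson correlation
of the condensed upper triangles, with a one-sided (greater-or-equal)
permutation p-value using the standard +1 correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import h5py
import numpy as np

from . import __version__
from .errors import ArtifactError
from .ordination import OrdinationResult

__all__ = [
    "DistanceMatrixArtifact",
    "write_artifact",
    "read_artifact",
    "read_distance",
    "mantel",
]

_CHUNK = 256


@dataclass
class DistanceMatrixArtifact:
    """Symmetric distance matrix plus ids, optional ordination, provenance."""

    sample_ids: np.ndarray
    matrix: np.ndarray
    ordination: OrdinationResult | None = None
    method: str = "unknown"
    alpha: float | None = None
    precision: str = "fp64"

    def __post_init__(self):
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.matrix = np.asarray(self.matrix)
        n = len(self.sample_ids)
        if self.matrix.shape != (n, n):
            raise ArtifactError("matrix shape does not match sample ids")
        if len(set(self.sample_ids)) != n:
            raise ArtifactError("duplicate sample ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def validate(self):
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ArtifactError("distance matrix is not symmetric")
        if np.any(np.diagonal(self.matrix) != 0):
            raise ArtifactError("distance matrix diagonal is not zero")
        if np.any(~np.isfinite(self.matrix)) or np.any(self.matrix < 0):
            raise ArtifactError("distances must be finite and non-negative")
        return self

    def index_of(self, key) -> int:
        if isinstance(key, (int, np.integer)):
            return int(key)
        hits = np.flatnonzero(self.sample_ids == key)
        if len(hits) != 1:
            raise ArtifactError(f"unknown sample id {key!r}")
        return int(hits[0])

    def condensed(self) -> np.ndarray:
        iu = np.triu_indices(self.n_samples, k=1)
        return np.asarray(self.matrix, dtype=np.float64)[iu]


def write_artifact(artifact: DistanceMatrixArtifact, path) -> None:
    """Write a validated artifact to the HDF5 container layout."""
    artifact.validate()
    n = artifact.n_samples
    chunk = min(_CHUNK, n)
    str_dt = h5py.string_dtype(encoding="utf-8")
    with h5py.File(path, "w") as fh:
        fh.create_dataset("order", data=np.asarray(
            [str(s) for s in artifact.sample_ids], dtype=object), dtype=str_dt)
        fh.create_dataset("matrix", data=artifact.matrix,
                          chunks=(chunk, chunk))
        fh.attrs["method"] = artifact.method
        fh.attrs["precision"] = artifact.precision
        fh.attrs["version"] = __version__
        if artifact.alpha is not None:
            fh.attrs["alpha"] = float(artifact.alpha)
        if artifact.ordination is not None:
            g = fh.create_group("pcoa")
            g.create_dataset("eigvals", data=artifact.ordination.eigvals)
            g.create_dataset("samples", data=artifact.ordination.samples)
            g.create_dataset("proportion_explained",
                             data=artifact.ordination.proportion_explained)


def read_artifact(path) -> DistanceMatrixArtifact:
    """Load a full artifact (ids, matrix, embedded ordination) from HDF5."""
    with h5py.File(path, "r") as fh:
        ids = np.asarray([s.decode() if isinstance(s, bytes) else s
                          for s in fh["order"][:]], dtype=object)
        matrix = fh["matrix"][:]
        ordination = None
        if "pcoa" in fh:
            g = fh["pcoa"]
            ordination = OrdinationResult(
                eigvals=g["eigvals"][:],
                samples=g["samples"][:],
                proportion_explained=g["proportion_explained"][:],
                sample_ids=ids,
            )
        return DistanceMatrixArtifact(
            sample_ids=ids, matrix=matrix, ordination=ordination,
            method=fh.attrs.get("method", "unknown"),
            alpha=float(fh.attrs["alpha"]) if "alpha" in fh.attrs else None,
            precision=fh.attrs.get("precision", "fp64"),
        )


def read_distance(path, i, j) -> float:
    """Random access to a single pair distance; ids or indices accepted.

    Reads only the id vector and the chunk(s) containing the probed cell —
    the matrix itself is never materialized.
    """
    with h5py.File(path, "r") as fh:
        if not isinstance(i, (int, np.integer)) or not isinstance(j, (int, np.integer)):
            ids = [s.decode() if isinstance(s, bytes) else s
                   for s in fh["order"][:]]
            index = {s: t for t, s in enumerate(ids)}
            try:
                i = i if isinstance(i, (int, np.integer)) else index[str(i)]
                j = j if isinstance(j, (int, np.integer)) else index[str(j)]
            except KeyError as exc:
                raise ArtifactError(f"unknown sample id {exc.args[0]!r}") from exc
        ds = fh["matrix"]
        n = ds.shape[0]
        if not (0 <= i < n and 0 <= j < n):
            raise ArtifactError(f"index out of range for {n} samples")
        return float(ds[int(i), int(j)])


def _align(a: DistanceMatrixArtifact, b: DistanceMatrixArtifact) -> np.ndarray:
    if set(a.sample_ids) != set(b.sample_ids):
        raise ArtifactError("Mantel requires identical sample id sets")
    pos = {s: t for t, s in enumerate(b.sample_ids)}
    perm = np.array([pos[s] for s in a.sample_ids])
    return np.asarray(b.matrix, dtype=np.float64)[np.ix_(perm, perm)]


def mantel(a: DistanceMatrixArtifact, b: DistanceMatrixArtifact,
           permutations: int = 999, seed: int = 0) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same samples.

    Returns ``(r, p)``: Pearson correlation of the condensed upper
    triangles (after aligning ``b`` to ``a``'s id order) and the one-sided
    permutation p-value ``(1 + #{r_perm >= r}) / (1 + permutations)``
    obtained by permuting one matrix's sample order.
    """
    if permutations < 1:
        raise ArtifactError("permutations must be >= 1")
    am = np.asarray(a.matrix, dtype=np.float64)
    bm = _align(a, b)
    n = am.shape[0]
    iu = np.triu_indices(n, k=1)
    x = am[iu]
    y = bm[iu]
    r = float(np.corrcoef(x, y)[0, 1])
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        p = rng.permutation(n)
        yp = bm[np.ix_(p, p)][iu]
        if np.corrcoef(x, yp)[0, 1] >= r:
            hits += 1
    return r, (1 + hits) / (1 + permutations)
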