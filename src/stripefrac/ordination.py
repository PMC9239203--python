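"""Principal coordinates, convex-hull occupancy and sparsity scaling.

PCoA embeds a distance matrix into Euclidean axes: square the distances,
double-center with the Gower projector ``B = -1/2 J (D*D) J``, and take the
symmetric eigendecomposition.  Coordinates are eigenvectors scaled by the
square root of their (positive) eigenvalues; non-Euclidean distance
matrices produce negative eigenvalues, which are dropped rather than
corrected, and explained proportions are taken over the positive spectrum.

The hull analysis asks how much of the occupied ordination space each
environment covers: resample a fixed number of samples per environment
(with replacement), take the 3-D convex hull volume over the first three
axes, and normalize by the hull volume of the full sample set.  The
sparsity analysis tracks the zero fraction of the feature table as more
samples of an environment are accumulated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.spatial import ConvexHull, QhullError

from .errors import ArtifactError
from .table import FeatureTable, sparsity

__all__ = [
    "OrdinationResult",
    "pcoa",
    "HullReport",
    "convex_hull_fractions",
    "sparsity_curve",
]


@dataclass
class OrdinationResult:
    """Eigenvalues (non-increasing), N x k coordinates, explained fractions."""

    eigvals: np.ndarray
    samples: np.ndarray
    proportion_explained: np.ndarray
    sample_ids: np.ndarray | None = None

    @property
    def n_axes(self) -> int:
        return self.samples.shape[1]


def _as_matrix(d):
    m = getattr(d, "matrix", d)
    m = np.asarray(m, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ArtifactError("distance input must be a square matrix")
    return m


def pcoa(d, n_axes: int | None = None) -> OrdinationResult:
    """Principal coordinates of a distance matrix (artifact or ndarray).

    Returns at most ``n_axes`` axes (default: all axes with positive
    eigenvalue).  Asking for more axes than the positive spectrum affords
    truncates with a warning.
    """
    D = _as_matrix(d)
    n = D.shape[0]
    if n_axes is not None and not 1 <= n_axes <= n - 1:
        raise ArtifactError(f"n_axes must be in [1, {n - 1}]")
    A = -0.5 * D * D
    # Gower double centering: B = J A J with J = I - 11'/n
    row = A.mean(axis=1, keepdims=True)
    col = A.mean(axis=0, keepdims=True)
    B = A - row - col + A.mean()
    eigvals, eigvecs = scipy.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    # numerical-zero floor: eigh returns O(n*eps*||B||) noise around 0
    tol = np.abs(eigvals).max() * n * np.finfo(np.float64).eps \
        if eigvals.size else 0.0
    pos = eigvals > tol
    n_pos = int(pos.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    if n_axes is not None and n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; "
            f"truncating", stacklevel=2)
    lam = eigvals[:k]
    coords = eigvecs[:, :k] * np.sqrt(lam)
    total = eigvals[pos].sum()
    prop = lam / total if total > 0 else np.zeros(k)
    ids = getattr(d, "sample_ids", None)
    return OrdinationResult(eigvals=lam, samples=coords,
                            proportion_explained=prop,
                            sample_ids=None if ids is None else np.asarray(ids))


@dataclass
class HullReport:
    """Normalized hull-volume fractions per environment.

    ``fractions`` maps each qualifying environment label to its replicate
    hull-volume fractions (subset hull volume over total hull volume);
    ``mean`` holds the per-environment replicate means.
    """

    fractions: dict
    mean: dict
    total_volume: float
    subset: int
    reps: int


def _hull_volume(points: np.ndarray) -> float:
    try:
        return float(ConvexHull(points).volume)
    except QhullError:
        warnings.warn("degenerate (coplanar) point set; hull volume 0",
                      stacklevel=3)
        return 0.0


def convex_hull_fractions(coords: OrdinationResult, labels,
                          subset: int = 1000, reps: int = 10,
                          min_group: int = 1000,
                          seed: int = 0) -> HullReport:
    """Per-environment convex-hull occupancy of the first three axes.

    ``labels`` maps sample (by id if the ordination carries ids, else by
    position) to an environment label.  For each environment with at least
    ``min_group`` samples, ``subset`` samples are drawn with replacement
    ``reps`` times; each replicate's 3-D hull volume is divided by the hull
    volume of all samples.  Defaults (1,000-sample subsets, 10 replicates,
    1,000-sample minimum) follow large-scale meta-analysis practice.
    """
    if coords.n_axes < 3:
        raise ArtifactError("convex hulls need at least 3 ordination axes")
    pts = coords.samples[:, :3]
    labels = pd.Series(labels)
    if coords.sample_ids is not None and not labels.index.equals(
            pd.RangeIndex(len(labels))):
        labels = labels.reindex(coords.sample_ids)
        if labels.isna().any():
            raise ArtifactError("labels missing for some samples")
    lab = labels.to_numpy()
    if len(lab) != len(pts):
        raise ArtifactError("label count does not match sample count")
    total = _hull_volume(pts)
    if total <= 0:
        raise ArtifactError("total hull volume is zero; ordination degenerate")
    rng = np.random.default_rng(seed)
    fractions, means = {}, {}
    for env in pd.unique(lab):
        members = np.flatnonzero(lab == env)
        if len(members) < min_group:
            continue
        fr = []
        for _ in range(reps):
            pick = rng.choice(members, size=subset, replace=True)
            fr.append(_hull_volume(pts[pick]) / total)
        fractions[env] = np.array(fr)
        means[env] = float(np.mean(fr))
    return HullReport(fractions=fractions, mean=means, total_volume=total,
                      subset=subset, reps=reps)


def sparsity_curve(table: FeatureTable, labels, min_group: int = 1000,
                   steps=None, reps: int = 10, seed: int = 0,
                   drop_empty_features: bool = False) -> pd.DataFrame:
    """Mean table sparsity as a function of accumulated sample count.

    For each environment with at least ``min_group`` samples and each step
    size ``n`` (default powers of two, 64..8192), draw ``n`` samples without
    replacement ``reps`` times and compute the zero fraction of the
    resulting sub-table.  By default the full feature axis is kept (all-zero
    feature rows are *not* dropped), so the denominator is the dense size a
    table of those samples over the complete feature set would have; set
    ``drop_empty_features`` to restrict to features observed in the subset.

    Returns a tidy DataFrame with columns environment, n_samples, mean and
    the per-replicate values.
    """
    if steps is None:
        steps = [2 ** p for p in range(6, 14)]  # 64 .. 8192
    labels = pd.Series(labels)
    lab = labels.reindex(table.sample_ids).to_numpy() \
        if not labels.index.equals(pd.RangeIndex(len(labels))) else labels.to_numpy()
    if len(lab) != table.shape[1]:
        raise ArtifactError("label count does not match sample count")
    rng = np.random.default_rng(seed)
    rows = []
    for env in pd.unique(lab):
        members = np.flatnonzero(lab == env)
        if len(members) < min_group:
            continue
        for n in steps:
            if n > len(members):
                warnings.warn(
                    f"step {n} exceeds group size {len(members)} for "
                    f"{env!r}; skipped", stacklevel=2)
                continue
            vals = []
            for _ in range(reps):
                pick = rng.choice(members, size=n, replace=False)
                sub = FeatureTable(table.feature_ids, table.sample_ids[pick],
                                   table.counts[:, pick])
                if drop_empty_features:
                    sub = sub.drop_empty_features()
                vals.append(sparsity(sub))
            rows.append({"environment": env, "n_samples": n,
                         "mean_sparsity": float(np.mean(vals)),
                         "replicates": np.array(vals)})
    return pd.DataFrame(rows, columns=["environment", "n_samples",
                                       "mean_sparsity", "replicates"])
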