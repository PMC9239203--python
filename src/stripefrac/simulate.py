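"""Synthetic trees and sparse tables, plus the brute-force UniFrac oracle.

Real amplicon surveys pair a large insertion tree with a count table whose
sparsity grows with sample count (well past 99.8% for big meta-analyses)
and whose samples are rarefied to a common depth (500 here).  The
generators emulate exactly that regime: random bifurcating trees with
exponential branch lengths, and tables in which each sample draws a small
environment-biased feature support and multinomial counts summing to a
fixed depth.  Environments use overlapping Dirichlet-weighted feature
pools so ordinations of the result have real group structure.

``oracle_unifrac`` is the deliberately naive reference: dense vectors, a
fresh root-ward walk per leaf, one explicit formula evaluation per pair,
no striping, no sparsity tricks, fp64 only.  Every engine configuration is
tested against it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import StripefracError
from .h5dm import DistanceMatrixArtifact
from .kernels import VariantParams
from .phylo import PhyloTree, parse_newick
from .table import FeatureTable

__all__ = ["SimConfig", "random_tree", "random_table", "oracle_unifrac"]


@dataclass(frozen=True)
class SimConfig:
    """Knobs for the synthetic data regime.

    Defaults mirror a rarefied 16S survey scaled to desk size: depth 500
    counts per sample, ~99% zero cells, a handful of environments with
    overlapping feature pools, exponential branch lengths of mean 0.1
    (the magnitude typical of substitution-scaled amplicon trees).
    """

    n_leaves: int = 512
    n_samples: int = 64
    target_sparsity: float = 0.99
    depth: int = 500
    mean_branch: float = 0.1
    n_environments: int = 3
    seed: int = 0

    def __post_init__(self):
        if min(self.n_leaves, self.n_samples, self.depth,
               self.n_environments) < 1 or self.mean_branch <= 0:
            raise StripefracError("all simulation sizes must be positive")
        if not 0.0 <= self.target_sparsity < 1.0:
            raise StripefracError("target_sparsity must be in [0, 1)")


def random_tree(n_leaves: int, seed: int = 0,
                mean_branch: float = 0.1) -> PhyloTree:
    """Random bifurcating tree over leaves ``L0..L{n-1}``.

    Built by repeated random joins (each join creating one internal
    vertex), giving ``2 n - 1`` vertices; branch lengths are exponential
    with mean ``mean_branch``.  Bit-for-bit reproducible per seed.
    """
    if n_leaves < 1:
        raise StripefracError("need at least one leaf")
    rng = np.random.default_rng([int(seed), 0x7ee])
    subtrees = [f"L{i}" for i in range(n_leaves)]
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        bl, br = rng.exponential(mean_branch, size=2)
        subtrees.append(f"({left}:{bl:.9g},{right}:{br:.9g})")
    if n_leaves == 1:
        return parse_newick(f"({subtrees[0]}:{rng.exponential(mean_branch):.9g});")
    return parse_newick(subtrees[0] + ";")


def random_table(cfg: SimConfig) -> tuple[FeatureTable, pd.Series]:
    """Sparse count table plus environment labels under ``cfg``.

    Each sample belongs to an environment (round-robin); every environment
    has its own Dirichlet weight vector over all features.  A sample picks
    ``round((1 - target_sparsity) * n_leaves)`` support features (weighted,
    without replacement) and distributes exactly ``depth`` counts over them
    multinomially, so column sums equal the depth by construction.
    """
    rng = np.random.default_rng([int(cfg.seed), 0x7ab1e])
    n_feat, n_samp = cfg.n_leaves, cfg.n_samples
    support = int(round((1.0 - cfg.target_sparsity) * n_feat))
    if support < 1:
        raise StripefracError(
            f"target sparsity {cfg.target_sparsity} leaves no support for "
            f"{n_feat} features")
    # overlapping environment pools: sparse-ish Dirichlet over all features
    env_w = rng.dirichlet(np.full(n_feat, 0.1), size=cfg.n_environments)
    rows, cols, data = [], [], []
    envs = np.array([f"env{s % cfg.n_environments}" for s in range(n_samp)])
    for s in range(n_samp):
        w = env_w[s % cfg.n_environments]
        pick = rng.choice(n_feat, size=support, replace=False,
                          p=w / w.sum())
        pw = w[pick]
        counts = rng.multinomial(cfg.depth, pw / pw.sum())
        nz = counts > 0
        rows.extend(pick[nz])
        cols.extend([s] * int(nz.sum()))
        data.extend(counts[nz])
    counts = sp.csr_matrix((np.asarray(data, dtype=np.float64),
                            (rows, cols)), shape=(n_feat, n_samp))
    feature_ids = np.array([f"L{i}" for i in range(n_feat)], dtype=object)
    sample_ids = np.array([f"S{s}" for s in range(n_samp)], dtype=object)
    table = FeatureTable(feature_ids, sample_ids, counts)
    return table, pd.Series(envs, index=sample_ids, name="environment")


def oracle_unifrac(table: FeatureTable, tree: PhyloTree,
                   params: VariantParams) -> DistanceMatrixArtifact:
    """Naive per-pair UniFrac over dense vectors; the testing ground truth."""
    if isinstance(params, str):
        params = VariantParams(params)
    n_vert, n_samp = tree.n_vertices, len(table.sample_ids)
    counts = table.dense()
    totals = counts.sum(axis=0)
    mass = np.zeros((n_vert, n_samp))
    for fi, f in enumerate(table.feature_ids):  # root-ward walk per leaf
        v = tree.leaf_vertex(f)
        while v != -1:
            mass[v] += counts[fi]
            v = int(tree.parent[v])
    b = tree.branch_length
    D = np.zeros((n_samp, n_samp))
    for i in range(n_samp):
        for j in range(i + 1, n_samp):
            u, v = mass[:, i], mass[:, j]
            if params.variant == "unweighted":
                x, y = u > 0, v > 0
                num = (b * (x != y)).sum()
                den = (b * (x | y)).sum()
            elif params.variant in ("weighted_unnormalized",
                                    "weighted_normalized"):
                ti = totals[i] if totals[i] > 0 else 1.0
                tj = totals[j] if totals[j] > 0 else 1.0
                pu, pv = u / ti, v / tj
                num = (b * np.abs(pu - pv)).sum()
                den = ((b * (pu + pv)).sum()
                       if params.variant == "weighted_normalized" else 1.0)
            elif params.variant == "generalized":
                ti = totals[i] if totals[i] > 0 else 1.0
                tj = totals[j] if totals[j] > 0 else 1.0
                pu, pv = u / ti, v / tj
                s = pu + pv
                num = den = 0.0
                for t in range(n_vert):
                    if s[t] > 0:
                        num += b[t] * s[t] ** params.alpha * abs(pu[t] - pv[t]) / s[t]
                        den += b[t] * s[t] ** params.alpha
            else:  # variance_adjusted
                m = totals[i] + totals[j]
                mi = u + v
                num = den = 0.0
                for t in range(n_vert):
                    if 0 < mi[t] < m:
                        w = 1.0 / np.sqrt(mi[t] * (m - mi[t]))
                        num += b[t] * abs(u[t] - v[t]) * w
                        den += b[t] * mi[t] * w
            D[i, j] = D[j, i] = num / den if den > 0 else 0.0
    return DistanceMatrixArtifact(sample_ids=table.sample_ids.copy(),
                                  matrix=D, method=params.variant,
                                  alpha=params.alpha, precision="fp64")
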