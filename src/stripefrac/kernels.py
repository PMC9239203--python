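"""Per-pair UniFrac kernels and their sparse-aware / bit-packed supports.

The computation has two stages.  *Embedding* propagates each sample's mass
from the tips to the root, producing a vertices x samples matrix ``u`` in
which row *i* holds, for every sample, the total mass found below edge *i*.
Every UniFrac variant is then a ratio of two sums over edges of
``b_i * f(u_i, v_i)`` for a pair of embedded columns ``(u, v)``:

========================  ====================================================
unweighted                sum b_i [u_i xor v_i present] / sum b_i [u_i or v_i]
weighted (unnormalized)   sum b_i |u_i - v_i|                (u, v proportions)
weighted (normalized)     sum b_i |u_i - v_i| / sum b_i (u_i + v_i)
generalized(alpha)        sum b_i (u_i+v_i)^(alpha-1) |u_i-v_i|
                          / sum b_i (u_i+v_i)^alpha
variance-adjusted         sum b_i |u_i-v_i| / sqrt(m_i (m - m_i))
                          / sum b_i (u_i+v_i) / sqrt(m_i (m - m_i))
========================  ====================================================

where ``m_i`` is the pair's combined count at vertex *i* and ``m`` the pair's
total count; vertices with ``m_i`` equal to 0 or ``m`` contribute nothing.
The root edge has length 0 and therefore never contributes.

Microbiome tables are extremely sparse, so most embedded entries are zero
and contribute nothing to either sum.  Two accelerations exploit this:
*zero maps* (per-vertex indices of the samples with mass, letting kernels
skip zero work) and, for the presence/absence unweighted variant, *bit
packing* (64 samples per machine word, XOR/OR plus popcount lookups over
16-bit blocks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import TreeTableMismatchError, VariantError
from .phylo import PhyloTree
from .table import FeatureTable

__all__ = [
    "VariantParams",
    "EmbeddedTable",
    "ZeroMap",
    "BitMatrix",
    "embed",
    "mode_for_variant",
    "pair_distance",
    "build_zero_maps",
    "pack_presence_bits",
    "unpack_presence_bits",
    "popcount",
    "unweighted_bitpacked",
]

VARIANTS = (
    "unweighted",
    "weighted_unnormalized",
    "weighted_normalized",
    "generalized",
    "variance_adjusted",
)

_MODE_FOR_VARIANT = {
    "unweighted": "presence",
    "weighted_unnormalized": "proportion",
    "weighted_normalized": "proportion",
    "generalized": "proportion",
    "variance_adjusted": "count",
}


@dataclass(frozen=True)
class VariantParams:
    """UniFrac variant selector; ``alpha`` applies to generalized only."""

    variant: str
    alpha: float | None = None

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise VariantError(
                f"unknown variant {self.variant!r}; choose one of {VARIANTS}")
        if self.variant == "generalized":
            if self.alpha is None:
                raise VariantError("generalized UniFrac requires alpha")
            if not 0.0 <= self.alpha <= 1.0:
                raise VariantError("alpha must be in [0, 1]")
        elif self.alpha is not None:
            raise VariantError(f"alpha is only meaningful for generalized "
                               f"UniFrac, not {self.variant}")


def mode_for_variant(variant: str) -> str:
    """Embedding mode (proportion/count/presence) each variant consumes."""
    return _MODE_FOR_VARIANT[variant]


@dataclass
class EmbeddedTable:
    """Vertices x samples matrix of propagated sample mass.

    ``values[i, s]`` is the total mass of sample *s* at or below vertex *i*:
    proportions, raw counts, or presence (float 0/1) depending on ``mode``.
    Rows follow the tree's postorder; ``branch_length`` is aligned to rows.
    ``sample_totals`` holds the original per-sample count totals (needed by
    the variance-adjusted variant).
    """

    values: np.ndarray
    branch_length: np.ndarray
    mode: str
    sample_ids: np.ndarray
    sample_totals: np.ndarray

    @property
    def n_vertices(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]


def embed(table: FeatureTable, tree: PhyloTree, mode: str,
          drop_unmapped: bool = False) -> EmbeddedTable:
    """Propagate table columns from tree tips to the root.

    Each feature is placed on its matching tip, then a single forward pass
    over the postorder ``parent`` array accumulates children into parents
    (children precede parents, so ``values[parent[i]] += values[i]`` in
    index order is a complete propagation).

    Features absent from the tree raise :class:`TreeTableMismatchError`
    unless ``drop_unmapped`` is set, mirroring a pipeline in which dropping
    unplaced features is a deliberate step.
    """
    if mode not in ("proportion", "count", "presence"):
        raise VariantError(f"unknown embedding mode {mode!r}")
    missing = [f for f in table.feature_ids if f not in tree._leaf_index]
    if missing:
        if not drop_unmapped:
            raise TreeTableMismatchError(
                f"{len(missing)} feature(s) not found in tree: "
                f"{', '.join(map(str, missing[:10]))}"
                + ("..." if len(missing) > 10 else ""))
        keep = np.array([f not in set(missing) for f in table.feature_ids])
        table = FeatureTable(table.feature_ids[keep], table.sample_ids,
                             table.counts[keep])

    n_vert, n_samp = tree.n_vertices, len(table.sample_ids)
    totals = table.sample_sums()
    vals = np.zeros((n_vert, n_samp), dtype=np.float64)
    rows = np.array([tree.leaf_vertex(f) for f in table.feature_ids], dtype=np.int64)
    dense = table.counts.toarray()
    if mode == "proportion":
        nz = totals > 0
        dense = dense.copy()
        dense[:, nz] /= totals[nz]
    elif mode == "presence":
        dense = (dense > 0).astype(np.float64)
    if len(rows):
        vals[rows] = dense
    parent = tree.parent
    if mode == "presence":
        for i in range(n_vert - 1):
            np.maximum(vals[parent[i]], vals[i], out=vals[parent[i]])
    else:
        for i in range(n_vert - 1):
            vals[parent[i]] += vals[i]
    return EmbeddedTable(values=vals, branch_length=tree.branch_length.copy(),
                         mode=mode, sample_ids=table.sample_ids.copy(),
                         sample_totals=totals)


# ---------------------------------------------------------------------------
# Reference per-pair kernel

def _check_mode(params: VariantParams, mode: str):
    want = _MODE_FOR_VARIANT[params.variant]
    if mode != want:
        raise VariantError(
            f"{params.variant} requires {want}-mode embedding, got {mode}")


def pair_distance(u: np.ndarray, v: np.ndarray, b: np.ndarray,
                  params: VariantParams,
                  totals: tuple[float, float] | None = None) -> float:
    """Distance between two embedded columns (the scalar reference kernel).

    ``u`` and ``v`` must be aligned to the same postorder and in the mode the
    variant consumes (presence for unweighted, proportions for the weighted
    family, counts plus ``totals`` for variance-adjusted).  A 0/0 ratio —
    two empty samples, or no observed tree mass — is defined as distance 0.
    """
    u = np.asarray(u, dtype=np.float64)
    v = np.asarray(v, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    variant = params.variant
    if variant == "unweighted":
        x = (u > 0).astype(np.float64)
        y = (v > 0).astype(np.float64)
        num = float(b @ np.abs(x - y))          # xor
        den = float(b @ np.maximum(x, y))       # or
    elif variant == "weighted_unnormalized":
        return float(b @ np.abs(u - v))
    elif variant == "weighted_normalized":
        num = float(b @ np.abs(u - v))
        den = float(b @ (u + v))
    elif variant == "generalized":
        s = u + v
        pos = s > 0
        num = float(b[pos] @ (s[pos] ** (params.alpha - 1.0)
                              * np.abs(u - v)[pos]))
        den = float(b[pos] @ (s[pos] ** params.alpha))
    elif variant == "variance_adjusted":
        if totals is None:
            raise VariantError("variance_adjusted requires sample count totals")
        m = float(totals[0]) + float(totals[1])
        mi = u + v
        ok = (mi > 0) & (mi < m)
        w = 1.0 / np.sqrt(mi[ok] * (m - mi[ok]))
        num = float(b[ok] @ (np.abs(u - v)[ok] * w))
        den = float(b[ok] @ (mi[ok] * w))
    else:  # pragma: no cover
        raise VariantError(variant)
    if den == 0.0:
        if num != 0.0:
            raise VariantError("nonzero numerator with zero denominator")
        warnings.warn("0/0 UniFrac denominator; defining distance as 0",
                      stacklevel=2)
        return 0.0
    return num / den


# ---------------------------------------------------------------------------
# Zero maps (sparse-aware support)

@dataclass
class ZeroMap:
    """Per-vertex nonzero-sample indices plus per-block all-zero flags.

    ``nonzero[i]`` lists the samples with mass at vertex *i*;
    ``block_all_zero[t]`` is True when no vertex in block *t* (of
    ``block`` consecutive postorder vertices) has any mass at all, letting
    kernels skip the whole block.
    """

    nonzero: list
    nonzero_mask: np.ndarray
    block: int
    block_all_zero: np.ndarray


def build_zero_maps(emb: EmbeddedTable, block: int = 64) -> ZeroMap:
    """One-pass precalculation of which (vertex, sample) entries carry mass."""
    mask = emb.values != 0
    nonzero = [np.flatnonzero(mask[i]) for i in range(emb.n_vertices)]
    n_blocks = (emb.n_vertices + block - 1) // block
    flags = np.zeros(n_blocks, dtype=bool)
    row_any = mask.any(axis=1)
    for t in range(n_blocks):
        flags[t] = not row_any[t * block:(t + 1) * block].any()
    return ZeroMap(nonzero=nonzero, nonzero_mask=mask, block=block,
                   block_all_zero=flags)


# ---------------------------------------------------------------------------
# Bit packing (unweighted variant)

# 16-bit popcount lookup: the classic memory/compute trade-off.  _BITS16
# additionally expands a 16-bit block into its 16 bits so whole stripes of
# sample pairs can be processed per vertex with one table lookup per block.
_POP16 = None
_BITS16 = None


def _luts():
    global _POP16, _BITS16
    if _POP16 is None:
        idx = np.arange(65536, dtype=np.uint16)
        _BITS16 = ((idx[:, None] >> np.arange(16)) & 1).astype(np.uint8)
        _POP16 = _BITS16.sum(axis=1).astype(np.uint8)
    return _POP16, _BITS16


@dataclass
class BitMatrix:
    """Presence bits packed 64 samples per word, vertices x words.

    Bit ``s % 64`` of ``words[i, s // 64]`` is set iff sample *s* has any
    mass at vertex *i*.  Tail bits beyond ``n_samples`` are zero.
    """

    words: np.ndarray
    n_samples: int

    @property
    def n_vertices(self) -> int:
        return self.words.shape[0]


def popcount(words: np.ndarray) -> np.ndarray:
    """Per-word set-bit counts via the 16-bit lookup table."""
    pop16, _ = _luts()
    w16 = np.ascontiguousarray(words).view(np.uint16)
    return pop16[w16].astype(np.int64).reshape(words.shape + (-1,)).sum(axis=-1)


def pack_presence_bits(emb: EmbeddedTable) -> BitMatrix:
    """Pack a presence-mode embedding into 64-sample machine words."""
    if emb.mode != "presence":
        raise VariantError("bit packing requires a presence-mode embedding")
    n = emb.n_samples
    bits = (emb.values > 0).astype(np.uint8)
    pad = (-n) % 64
    if pad:
        bits = np.concatenate(
            [bits, np.zeros((emb.n_vertices, pad), dtype=np.uint8)], axis=1)
    packed = np.packbits(bits, axis=1, bitorder="little")
    words = np.ascontiguousarray(packed).view("<u8")
    return BitMatrix(words=words, n_samples=n)


def unpack_presence_bits(bm: BitMatrix) -> np.ndarray:
    """Inverse of :func:`pack_presence_bits` (boolean vertices x samples)."""
    bytes_ = np.ascontiguousarray(bm.words).view(np.uint8)
    bits = np.unpackbits(bytes_, axis=1, bitorder="little")
    return bits[:, :bm.n_samples].astype(bool)


def _bit_columns(bm: BitMatrix, samples: np.ndarray) -> np.ndarray:
    """Extract per-sample bit columns (vertices x len(samples), uint8)."""
    _, bits16 = _luts()
    w16 = np.ascontiguousarray(bm.words).view(np.uint16)
    blk = samples // 16
    off = samples % 16
    return bits16[w16[:, blk], off]


def unweighted_bitpacked(bm: BitMatrix, b: np.ndarray, pairs) -> tuple:
    """Unweighted numerator/denominator sums for a list of sample pairs.

    For each pair ``(s, t)`` the numerator is ``sum_i b_i * bit_s(x_i xor
    y_i)`` and the denominator the same over OR, evaluated blockwise via the
    16-bit lookup table.  The arithmetic (one length-``n_vertices`` dot
    product per pair) matches the scalar kernel exactly, bit for bit.
    """
    pairs = np.asarray(pairs, dtype=np.int64).reshape(-1, 2)
    b = np.asarray(b, dtype=np.float64)
    xs = _bit_columns(bm, pairs[:, 0])
    ys = _bit_columns(bm, pairs[:, 1])
    xor = np.bitwise_xor(xs, ys)
    orr = np.bitwise_or(xs, ys)
    n_pairs = pairs.shape[0]
    num = np.empty(n_pairs, dtype=np.float64)
    den = np.empty(n_pairs, dtype=np.float64)
    # one dot product per pair, in the exact same form as the scalar
    # kernel's b @ bits, so the two routes agree bit for bit
    for p in range(n_pairs):
        num[p] = b @ xor[:, p].astype(np.float64)
        den[p] = b @ orr[:, p].astype(np.float64)
    return num, den
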