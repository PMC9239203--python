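"""Sparse feature tables: IO, rarefaction, normalization, sparsity.

A feature table holds non-negative counts of features (e.g. 16S amplicon
sequence variants) per sample.  Real microbiome tables are overwhelmingly
sparse — most features are absent from most samples — so counts are stored
as a ``scipy.sparse`` matrix with explicit zeros eliminated.

BIOM-HDF5 v2.1 IO goes through the ``biom`` package; TSV follows the common
amplicon dialect (features as rows, ``#OTU ID`` header cell accepted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import TableError

__all__ = [
    "FeatureTable",
    "read_table",
    "write_table",
    "rarefy",
    "relative_abundance",
    "sparsity",
]

DEFAULT_RAREFACTION_DEPTH = 500


def _check_ids(ids, what):
    ids = np.asarray(ids, dtype=object)
    if len(ids) != len(set(ids)):
        seen, dup = set(), set()
        for x in ids:
            (dup if x in seen else seen).add(x)
        raise TableError(f"duplicate {what} id(s): {sorted(map(str, dup))}")
    return ids


@dataclass
class FeatureTable:
    """Features x samples count matrix with explicit zeros dropped."""

    feature_ids: np.ndarray
    sample_ids: np.ndarray
    counts: sp.csr_matrix

    def __post_init__(self):
        self.feature_ids = _check_ids(self.feature_ids, "feature")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        m = sp.csr_matrix(self.counts)
        if m.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise TableError(
                f"counts shape {m.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if m.nnz and m.data.min() < 0:
            raise TableError("negative count values")
        m.eliminate_zeros()
        self.counts = m

    @property
    def shape(self):
        return self.counts.shape

    def dense(self) -> np.ndarray:
        return self.counts.toarray()

    def sample_sums(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def filter_samples(self, mask) -> "FeatureTable":
        return FeatureTable(self.feature_ids, self.sample_ids[mask],
                            self.counts[:, np.asarray(mask)])

    def drop_empty_features(self) -> "FeatureTable":
        keep = np.diff(self.counts.indptr) > 0
        return FeatureTable(self.feature_ids[keep], self.sample_ids,
                            self.counts[keep])


# ---------------------------------------------------------------------------
# IO

def _read_tsv(path) -> FeatureTable:
    with open(path) as fh:
        lines = fh.readlines()
    # a leading '# Constructed from biom file' style comment may precede the
    # header; the header itself may begin with '#OTU ID'
    start = 0
    while start < len(lines) - 1 and lines[start].startswith("#") and \
            lines[start + 1].startswith("#"):
        start += 1
    try:
        df = pd.read_csv(
            pd.io.common.StringIO("".join(lines[start:])),
            sep="\t", index_col=0, header=0,
        )
    except Exception as exc:
        raise TableError(f"malformed TSV table: {exc}") from exc
    if df.columns.size == 0 or df.index.size == 0:
        raise TableError("TSV table has no samples or no features")
    values = df.to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        raise TableError("non-numeric values in TSV table")
    if np.any(values < 0):
        raise TableError("negative values in TSV table")
    return FeatureTable(df.index.to_numpy(dtype=object),
                        df.columns.to_numpy(dtype=object),
                        sp.csr_matrix(values))


def _read_biom(path) -> FeatureTable:
    import biom

    try:
        t = biom.load_table(str(path))
    except Exception as exc:
        raise TableError(f"cannot load BIOM table: {exc}") from exc
    return FeatureTable(
        np.asarray(t.ids("observation"), dtype=object),
        np.asarray(t.ids("sample"), dtype=object),
        sp.csr_matrix(t.matrix_data),
    )


def read_table(path, format: str | None = None) -> FeatureTable:
    """Read a feature table from BIOM-HDF5 or TSV.

    ``format`` is ``'biom-hdf5'`` or ``'tsv'``; when None it is inferred
    from the file extension (``.biom`` / anything else).
    """
    if format is None:
        format = "biom-hdf5" if str(path).endswith(".biom") else "tsv"
    if format == "biom-hdf5":
        return _read_biom(path)
    if format == "tsv":
        return _read_tsv(path)
    raise TableError(f"unknown table format {format!r}")


def write_table(table: FeatureTable, path, format: str | None = None) -> None:
    """Write a feature table as BIOM-HDF5 or TSV (inferred from extension)."""
    if format is None:
        format = "biom-hdf5" if str(path).endswith(".biom") else "tsv"
    if format == "biom-hdf5":
        import biom
        import h5py

        t = biom.Table(table.counts, list(table.feature_ids),
                       list(table.sample_ids))
        with h5py.File(path, "w") as fh:
            t.to_hdf5(fh, generated_by="stripefrac")
    elif format == "tsv":
        df = pd.DataFrame(table.dense(), index=table.feature_ids,
                          columns=table.sample_ids)
        df.index.name = "#OTU ID"
        df.to_csv(path, sep="\t")
    else:
        raise TableError(f"unknown table format {format!r}")


# ---------------------------------------------------------------------------
# Transforms

def rarefy(table: FeatureTable, depth: int = DEFAULT_RAREFACTION_DEPTH,
           seed: int = 0) -> FeatureTable:
    """Subsample every sample to exactly ``depth`` counts without replacement.

    Samples with fewer than ``depth`` total counts are dropped; features left
    without any counts are removed.  Each retained sample draws from its own
    RNG stream derived from ``(seed, sample position)``, so results do not
    depend on which samples are dropped or on iteration order.

    The default depth of 500 controls for sequencing effort while keeping
    even shallow samples; it matches common practice for very large
    meta-analyses.
    """
    if depth < 1:
        raise TableError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    keep = sums >= depth
    if not keep.any():
        raise TableError(f"no sample reaches rarefaction depth {depth}")
    csc = table.counts.tocsc()
    cols = []
    kept_idx = np.flatnonzero(keep)
    for j in kept_idx:
        col = csc[:, j]
        rows = col.indices
        vals = col.data.astype(np.int64)
        if np.any(col.data != vals):
            raise TableError("rarefaction requires integer counts")
        rng = np.random.default_rng([int(seed), int(j)])
        drawn = rng.multivariate_hypergeometric(vals, depth)
        cols.append(sp.csc_matrix(
            (drawn[drawn > 0].astype(np.float64),
             (rows[drawn > 0], np.zeros(int((drawn > 0).sum()), dtype=int))),
            shape=(table.shape[0], 1)))
    counts = sp.hstack(cols, format="csr") if cols else sp.csr_matrix((table.shape[0], 0))
    out = FeatureTable(table.feature_ids, table.sample_ids[keep], counts)
    return out.drop_empty_features()


def relative_abundance(table: FeatureTable) -> FeatureTable:
    """Convert counts to per-sample proportions (each column sums to 1)."""
    sums = table.sample_sums()
    if np.any(sums <= 0):
        bad = table.sample_ids[sums <= 0]
        raise TableError(f"zero-sum sample(s): {list(map(str, bad))}")
    csc = table.counts.tocsc()
    norm = csc @ sp.diags(1.0 / sums)
    return FeatureTable(table.feature_ids, table.sample_ids, norm.tocsr())


def sparsity(table: FeatureTable) -> float:
    """Fraction of zero cells in the dense representation of the table."""
    r, c = table.shape
    if r == 0 or c == 0:
        raise TableError("sparsity of an empty table is undefined")
    return 1.0 - table.counts.nnz / (r * c)
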