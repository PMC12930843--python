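"""Peak-sequence embeddings and the LSI cell-embedding alternative.

The DNA language model used as feature extractor upstream is treated as an
exchangeable frozen embedder. Two concrete embedders are provided: a loader
for precomputed per-peak embedding tables (the route for embeddings produced
by an external model), and a deterministic k-mer count / random projection
embedder suitable for desk-scale experiments and simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from sklearn.decomposition import TruncatedSVD

from .io_formats import CellByPeakMatrix, FormatError

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass
class PeakEmbeddingMatrix:
    """N peaks x d numeric embeddings, rows aligned to peak_ids."""

    values: np.ndarray
    peak_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.peak_ids):
            raise ValueError("embedding rows must align with peak_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding entries must be finite")

    @property
    def dim(self):
        return self.values.shape[1]


@dataclass
class CellEmbeddingMatrix:
    """C cells x D numeric cell representations, rows aligned to cell_ids."""

    values: np.ndarray
    cell_ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.cell_ids):
            raise ValueError("embedding rows must align with cell_ids")
        if not np.isfinite(self.values).all():
            raise ValueError("embedding entries must be finite")


@dataclass
class EmbedderSpec:
    """Configuration of the pluggable peak-sequence embedder.

    kind 'kmer_projection' counts the 4**k possible k-mers per sequence
    (k-mers containing N are dropped), optionally L2-normalizes the count
    vector, then applies a seed-fixed random Gaussian projection to d
    dimensions. kind 'precomputed' loads rows from a TSV keyed by peak_id.
    ``projection='identity'`` is a test hook requiring d == 4**k.
    """

    kind: str = "kmer_projection"
    k: int = 4
    d: int = 512
    seed: int = 0
    normalize: bool = True
    projection: str = "random"
    path: str | None = None

    def __post_init__(self):
        if self.kind not in ("kmer_projection", "precomputed", "external_plugin"):
            raise ValueError(f"unknown embedder kind {self.kind!r}")
        if self.d < 1 or self.k < 1:
            raise ValueError("d and k must be >= 1")
        if self.projection == "identity" and self.d != 4 ** self.k:
            raise ValueError("identity projection requires d == 4**k")


def kmer_counts(sequence: str, k: int) -> np.ndarray:
    """Count vector over the 4**k lexicographic k-mers; N-containing dropped."""
    counts = np.zeros(4 ** k, dtype=np.float64)
    seq = sequence.upper()
    for i in range(len(seq) - k + 1):
        code = 0
        ok = True
        for ch in seq[i:i + k]:
            b = _BASE_CODE.get(ch)
            if b is None:
                ok = False
                break
            code = code * 4 + b
        if ok:
            counts[code] += 1
    return counts


def embed_peaks(sequences, spec: EmbedderSpec, peak_ids=None) -> PeakEmbeddingMatrix:
    """Embed peak sequences into an N x d matrix per the embedder spec."""
    sequences = list(sequences)
    if not sequences:
        raise ValueError("sequence list is empty")
    if peak_ids is None:
        peak_ids = [f"peak_{i}" for i in range(len(sequences))]
    bad = set("".join(sequences).upper()) - set("ACGTN")
    if bad:
        raise ValueError(f"sequences contain characters outside ACGTN: {sorted(bad)}")

    if spec.kind == "precomputed":
        return load_precomputed_embeddings(spec.path, peak_ids)
    if spec.kind != "kmer_projection":
        raise ValueError(f"embedder kind {spec.kind!r} requires an external plugin")

    counts = np.stack([kmer_counts(s, spec.k) for s in sequences])
    if spec.normalize:
        norms = np.linalg.norm(counts, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        counts = counts / norms
    if spec.projection == "identity":
        values = counts
    else:
        rng = np.random.default_rng(spec.seed)
        proj = rng.standard_normal((4 ** spec.k, spec.d)) / np.sqrt(spec.d)
        values = counts @ proj
    return PeakEmbeddingMatrix(values, peak_ids)


def load_precomputed_embeddings(path, peak_ids) -> PeakEmbeddingMatrix:
    """Load a dense embedding table (first column peak_id) reordered to peak_ids."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    missing = [p for p in peak_ids if p not in df.index]
    if missing:
        shown = ", ".join(missing[:10])
        raise KeyError(f"{len(missing)} peak_ids missing from embedding table: {shown}")
    return PeakEmbeddingMatrix(df.loc[list(peak_ids)].to_numpy(dtype=np.float64),
                               list(peak_ids))


def filter_peaks(m: CellByPeakMatrix, min_cells: int) -> CellByPeakMatrix:
    """Drop peaks detected in fewer than ``min_cells`` cells, preserving order."""
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    counts = np.asarray((m.values > 0).sum(axis=0)).ravel()
    keep = counts >= min_cells
    if not keep.any():
        raise FormatError("all peaks removed by min_cells filter")
    return CellByPeakMatrix(m.values[:, keep].tocsr(),
                            list(m.cell_ids),
                            [p for p, k in zip(m.peak_ids, keep) if k])


def lsi_embed_cells(m: CellByPeakMatrix, dim: int = 128, binarize: bool = True,
                    seed: int = 0) -> CellEmbeddingMatrix:
    """LSI cell embedding: binarize -> TF-IDF -> truncated SVD.

    TF divides each cell row by its total accessible-peak count; IDF scales
    peak j by log(1 + n_cells / n_cells_with_peak_j). The embedding is the
    top-``dim`` left singular vectors scaled by their singular values (U S).
    """
    n_cells, n_peaks = m.values.shape
    if dim > min(n_cells, n_peaks) - 1:
        raise ValueError(
            f"dim={dim} exceeds min(n_cells, n_peaks) - 1 = {min(n_cells, n_peaks) - 1}")
    x = m.values.copy().tocsr()
    if binarize:
        x.data = (x.data > 0).astype(np.float64)
    else:
        x = x.astype(np.float64)
    row_tot = np.asarray(x.sum(axis=1)).ravel()
    zero_rows = np.flatnonzero(row_tot == 0)
    if zero_rows.size:
        raise FormatError(f"cell {m.cell_ids[zero_rows[0]]!r} has no accessible peaks")
    tf = sp.diags(1.0 / row_tot) @ x
    df = np.asarray((m.values > 0).sum(axis=0)).ravel()
    idf = np.log(1.0 + n_cells / np.maximum(df, 1))
    tfidf = (tf @ sp.diags(idf)).tocsr()
    svd = TruncatedSVD(n_components=dim, algorithm="arpack", random_state=seed)
    emb = svd.fit_transform(tfidf)  # equals U * S for the top components
    return CellEmbeddingMatrix(emb, list(m.cell_ids))
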