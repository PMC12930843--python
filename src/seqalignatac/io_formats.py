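"""Readers and writers for the on-disk artifacts of the annotation pipeline.

Conventions are strict and uniform: BED coordinates are 0-based half-open,
peaks are unstranded (sequences always come from the forward strand),
MatrixMarket triplets are 1-based on disk, and label encodings are assigned
by sorted label order so they are independent of input row order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite


class FormatError(ValueError):
    """Malformed or inconsistent on-disk artifact."""


@dataclass
class PeakSet:
    """Genomic intervals defining the accessibility feature axis.

    Coordinates are 0-based half-open; ``peak_id`` defaults to the
    ``chrom:start-end`` rendering of the interval.
    """

    peak_ids: list[str]
    chroms: list[str]
    starts: np.ndarray
    ends: np.ndarray

    def __post_init__(self):
        self.starts = np.asarray(self.starts, dtype=np.int64)
        self.ends = np.asarray(self.ends, dtype=np.int64)
        n = len(self.peak_ids)
        if not (len(self.chroms) == len(self.starts) == len(self.ends) == n):
            raise FormatError("PeakSet field lengths differ")
        if n and ((self.starts < 0).any() or (self.starts >= self.ends).any()):
            raise FormatError("every peak requires 0 <= start < end")
        if len(set(self.peak_ids)) != n:
            raise FormatError("peak_id values must be unique")

    def __len__(self):
        return len(self.peak_ids)


@dataclass
class CellByPeakMatrix:
    """Sparse cells x peaks accessibility matrix with aligned identifiers."""

    values: sp.csr_matrix
    cell_ids: list[str]
    peak_ids: list[str]

    def __post_init__(self):
        self.values = sp.csr_matrix(self.values)
        if self.values.shape != (len(self.cell_ids), len(self.peak_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.cell_ids)} cells x {len(self.peak_ids)} peaks")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids")
        if len(set(self.peak_ids)) != len(self.peak_ids):
            raise FormatError("duplicate peak_ids")
        if self.values.nnz and self.values.data.min() < 0:
            raise FormatError("accessibility values must be non-negative")

    @property
    def n_cells(self):
        return len(self.cell_ids)

    @property
    def n_peaks(self):
        return len(self.peak_ids)


@dataclass
class LabelTable:
    """Cell-type labels with a deterministic sorted-order integer encoding."""

    cell_ids: list[str]
    labels: list[str]
    classes: list[str] = field(default=None)

    def __post_init__(self):
        if len(self.cell_ids) != len(self.labels):
            raise FormatError("cell_ids and labels lengths differ")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise FormatError("duplicate cell_ids in label table")
        if self.classes is None:
            self.classes = sorted(set(self.labels))
        index = {c: i for i, c in enumerate(self.classes)}
        self.label_indices = np.array([index[l] for l in self.labels], dtype=np.int64)

    @property
    def n_classes(self):
        return len(self.classes)


def read_peaks_bed(path) -> PeakSet:
    """Parse a BED3/BED4 file into a PeakSet (0-based half-open intervals)."""
    ids, chroms, starts, ends = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"line {lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if start < 0 or start >= end:
                raise FormatError(f"line {lineno}: requires 0 <= start < end")
            ids.append(fields[3] if len(fields) >= 4 else f"{chrom}:{start}-{end}")
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
    return PeakSet(ids, chroms, np.array(starts, dtype=np.int64),
                   np.array(ends, dtype=np.int64))


def write_peaks_bed(peaks: PeakSet, path):
    with open(path, "w") as fh:
        for pid, chrom, s, e in zip(peaks.peak_ids, peaks.chroms, peaks.starts, peaks.ends):
            if pid == f"{chrom}:{s}-{e}":
                fh.write(f"{chrom}\t{s}\t{e}\n")
            else:
                fh.write(f"{chrom}\t{s}\t{e}\t{pid}\n")


def extract_peak_sequences(peaks: PeakSet, genome_path) -> list[str]:
    """Extract forward-strand uppercase sequences for each peak from a FASTA."""
    from pyfaidx import Fasta

    genome = Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    seqs = []
    for pid, chrom, s, e in zip(peaks.peak_ids, peaks.chroms, peaks.starts, peaks.ends):
        if chrom not in genome:
            raise KeyError(f"chromosome {chrom!r} (peak {pid}) absent from FASTA")
        if e > len(genome[chrom]):
            raise IndexError(
                f"peak {pid} end {e} exceeds {chrom} length {len(genome[chrom])}")
        seqs.append(str(genome[chrom][s:e]))
    return seqs


def read_cell_peak_mtx(matrix_path, cells_path, peaks_path,
                       orientation: str = "peaks-as-rows") -> CellByPeakMatrix:
    """Read a MatrixMarket triplet plus barcode/peak sidecars.

    ``orientation`` names the on-disk row axis; the returned matrix is always
    cells x peaks (CellRanger-style files store peaks as rows, the default).
    """
    if orientation not in ("peaks-as-rows", "cells-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    mat = sp.csr_matrix(mmread(str(matrix_path)))
    cell_ids = _read_id_column(cells_path)
    peak_ids = _read_id_column(peaks_path)
    if orientation == "peaks-as-rows":
        mat = mat.T.tocsr()
    if mat.shape != (len(cell_ids), len(peak_ids)):
        raise FormatError(
            f"matrix is {mat.shape[0]} x {mat.shape[1]} after orientation, but "
            f"sidecars list {len(cell_ids)} cells and {len(peak_ids)} peaks")
    return CellByPeakMatrix(mat, cell_ids, peak_ids)


def write_cell_peak_mtx(m: CellByPeakMatrix, matrix_path, cells_path, peaks_path,
                        orientation: str = "peaks-as-rows"):
    mat = m.values.T if orientation == "peaks-as-rows" else m.values
    mmwrite(str(matrix_path), sp.coo_matrix(mat))
    with open(cells_path, "w") as fh:
        fh.write("".join(c + "\n" for c in m.cell_ids))
    with open(peaks_path, "w") as fh:
        fh.write("".join(p + "\n" for p in m.peak_ids))


def _read_id_column(path) -> list[str]:
    with open(path) as fh:
        ids = [line.rstrip("\n").split("\t")[0] for line in fh if line.strip()]
    return ids


def read_labels(path, cell_ids) -> LabelTable:
    """Read a two-column TSV (cell_id, label) reordered to match ``cell_ids``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError("label file needs at least cell_id and label columns")
    mapping = dict(zip(df.iloc[:, 0], df.iloc[:, 1]))
    missing = [c for c in cell_ids if c not in mapping]
    if missing:
        shown = ", ".join(missing[:10])
        raise KeyError(f"{len(missing)} cell_ids missing from label file: {shown}")
    return LabelTable(list(cell_ids), [mapping[c] for c in cell_ids])


def write_labels(path, table: LabelTable):
    pd.DataFrame({"cell_id": table.cell_ids, "label": table.labels}).to_csv(
        path, sep="\t", index=False)


def write_predictions(path, cell_ids, labels, probabilities, class_names):
    """Write per-cell predictions with one softmax-probability column per class."""
    probabilities = np.asarray(probabilities, dtype=np.float64)
    if probabilities.shape != (len(cell_ids), len(class_names)):
        raise FormatError("probability matrix shape mismatch")
    if not np.allclose(probabilities.sum(axis=1), 1.0, atol=1e-6):
        raise FormatError("probability rows must sum to 1 within 1e-6")
    df = pd.DataFrame({"cell_id": list(cell_ids), "predicted_label": list(labels)})
    for j, name in enumerate(class_names):
        df[f"prob_{name}"] = probabilities[:, j]
    df.to_csv(path, sep="\t", index=False)
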