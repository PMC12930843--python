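"""Desk-scale simulation of paired reference/query scATAC-seq datasets.

Each cell type owns a disjoint set of marker peaks opened with high
probability; all other peaks open at a low background rate (Bernoulli
accessibility, matching the binary targets every downstream consumer uses).
The query (target) domain adds platform-style batch effects: extra per-entry
dropout and a sequencing-depth scaling of the count layer. Marker peaks carry
a type-specific sequence motif planted in otherwise uniform-random DNA, so
the sequence-embedding route has signal to find. Target labels are returned
for evaluation only and are never an input to any training step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from sklearn.metrics import f1_score

from .io_formats import CellByPeakMatrix, LabelTable, PeakSet

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    n_types: int = 4
    cells_per_type_source: int = 100
    cells_per_type_target: int = 100
    n_peaks: int = 2000
    marker_fraction: float = 0.5
    p_open_marker: float = 0.8
    p_open_background: float = 0.05
    batch_dropout: float = 0.3
    depth_factor: float = 1.0
    peak_length: int = 200
    motif_length: int = 8
    seed: int = 0

    def __post_init__(self):
        if self.n_types < 2:
            raise ValueError("need at least 2 cell types")
        if not (0 < self.marker_fraction <= 1):
            raise ValueError("marker_fraction must be in (0, 1]")
        if not (0 <= self.p_open_background < self.p_open_marker <= 1):
            raise ValueError("requires 0 <= p_open_background < p_open_marker <= 1")
        if not (0 <= self.batch_dropout < 1):
            raise ValueError("batch_dropout must be in [0, 1)")
        if self.depth_factor <= 0:
            raise ValueError("depth_factor must be positive")
        if int(self.marker_fraction * self.n_peaks) < self.n_types:
            raise ValueError("marker_fraction * n_peaks leaves fewer marker peaks "
                             "than cell types")


def simulate_pair(cfg: SimConfig):
    """Simulate a (source, target) dataset pair with known cell types.

    Returns ``(source_matrix, source_labels, target_matrix, target_labels,
    peaks, sequences)``. Source and target share the peak axis and the
    generative type programs; only the batch effects differ.
    """
    rng = np.random.default_rng(cfg.seed)
    n_markers = int(cfg.marker_fraction * cfg.n_peaks)
    marker_peaks = rng.choice(cfg.n_peaks, size=n_markers, replace=False)
    # peak -> owning type (-1 = background)
    owner = np.full(cfg.n_peaks, -1, dtype=np.int64)
    owner[marker_peaks] = np.arange(n_markers) % cfg.n_types

    type_names = [f"type{t:02d}" for t in range(cfg.n_types)]
    motifs = ["".join(rng.choice(_BASES, size=cfg.motif_length))
              for _ in range(cfg.n_types)]

    def sample_domain(prefix, cells_per_type, dropout, depth):
        labels, rows = [], []
        for t in range(cfg.n_types):
            p = np.where(owner == t, cfg.p_open_marker, cfg.p_open_background)
            open_mat = rng.random((cells_per_type, cfg.n_peaks)) < p
            if dropout > 0:
                open_mat &= rng.random(open_mat.shape) >= dropout
            rows.append(open_mat)
            labels.extend([type_names[t]] * cells_per_type)
        values = sp.csr_matrix(np.vstack(rows).astype(np.float64) * depth)
        cell_ids = [f"{prefix}_cell{i:05d}" for i in range(values.shape[0])]
        return (CellByPeakMatrix(values, cell_ids, peak_ids),
                LabelTable(cell_ids, labels, classes=type_names))

    peak_ids = [f"chr1:{i * (cfg.peak_length + 100)}-"
                f"{i * (cfg.peak_length + 100) + cfg.peak_length}"
                for i in range(cfg.n_peaks)]
    starts = np.array([i * (cfg.peak_length + 100) for i in range(cfg.n_peaks)])
    peaks = PeakSet(peak_ids, ["chr1"] * cfg.n_peaks, starts, starts + cfg.peak_length)

    sequences = []
    for j in range(cfg.n_peaks):
        seq = rng.choice(_BASES, size=cfg.peak_length)
        if owner[j] >= 0:
            pos = rng.integers(0, cfg.peak_length - cfg.motif_length + 1)
            seq[pos:pos + cfg.motif_length] = list(motifs[owner[j]])
        sequences.append("".join(seq))

    source = sample_domain("src", cfg.cells_per_type_source, 0.0, 1.0)
    target = sample_domain("tgt", cfg.cells_per_type_target,
                           cfg.batch_dropout, cfg.depth_factor)
    return source[0], source[1], target[0], target[1], peaks, sequences


def ground_truth_report(predictions: LabelTable, truth: LabelTable) -> dict:
    """Accuracy and macro-F1 of predicted against true cell types.

    Macro-F1 averages per-class F1 over the union of true and predicted
    classes; a class with no true or no predicted instances scores 0.
    """
    if set(predictions.cell_ids) != set(truth.cell_ids):
        extra = set(predictions.cell_ids) ^ set(truth.cell_ids)
        shown = ", ".join(sorted(extra)[:10])
        raise KeyError(f"cell_id sets differ ({len(extra)} mismatches): {shown}")
    pred_map = dict(zip(predictions.cell_ids, predictions.labels))
    y_true = list(truth.labels)
    y_pred = [pred_map[c] for c in truth.cell_ids]
    classes = sorted(set(y_true) | set(y_pred))
    acc = float(np.mean([t == p for t, p in zip(y_true, y_pred)]))
    macro = float(f1_score(y_true, y_pred, labels=classes, average="macro",
                           zero_division=0))
    return {"accuracy": acc, "macro_f1": macro}
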