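"""End-to-end orchestration: matrices in, target annotations out.

Embeddings for the two domains are computed from one jointly fitted model
(or LSI decomposition) over the concatenated cell set sharing the peak axis,
so that source and target features live in a common coordinate system —
separately fitted embeddings would differ by arbitrary rotations and make
shared-weight graph transfer ill-posed. No target label ever enters this
path.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .cell_embedding import EncoderConfig, extract_cell_embeddings, train_encoder
from .domain_adaptation import GDAConfig, annotate, train_gda
from .graph_construction import build_knn_graph
from .io_formats import CellByPeakMatrix, LabelTable
from .sequence_embedding import (CellEmbeddingMatrix, EmbedderSpec, embed_peaks,
                                 filter_peaks, lsi_embed_cells)


def joint_cell_embeddings(source: CellByPeakMatrix, target: CellByPeakMatrix,
                          route: str = "lsi", *, lsi_dim: int = 128,
                          sequences=None, embedder_spec: EmbedderSpec | None = None,
                          encoder_cfg: EncoderConfig | None = None,
                          min_cells: int = 1, seed: int = 0):
    """Embed source and target cells jointly; returns (source_emb, target_emb).

    route 'lsi' runs binarize/TF-IDF/truncated-SVD on the stacked matrix;
    route 'sequence' embeds peak sequences and trains the accessibility
    predictor on the stacked matrix, reading embeddings off its output layer.
    """
    if list(source.peak_ids) != list(target.peak_ids):
        raise ValueError("source and target must share an identical peak axis")
    stacked = CellByPeakMatrix(sp.vstack([source.values, target.values]).tocsr(),
                               list(source.cell_ids) + list(target.cell_ids),
                               list(source.peak_ids))
    if min_cells > 0:
        stacked = filter_peaks(stacked, min_cells)
    if route == "lsi":
        emb = lsi_embed_cells(stacked, dim=lsi_dim, seed=seed)
    elif route == "sequence":
        if sequences is None:
            raise ValueError("route 'sequence' requires peak sequences")
        keep = set(stacked.peak_ids)
        seqs = [s for p, s in zip(source.peak_ids, sequences) if p in keep]
        spec = embedder_spec or EmbedderSpec()
        peak_emb = embed_peaks(seqs, spec, peak_ids=list(stacked.peak_ids))
        state = train_encoder(peak_emb, stacked, encoder_cfg or EncoderConfig())
        emb = extract_cell_embeddings(state, stacked.cell_ids)
    else:
        raise ValueError(f"unknown embedding route {route!r}")
    n_s = source.n_cells
    return (CellEmbeddingMatrix(emb.values[:n_s], list(source.cell_ids)),
            CellEmbeddingMatrix(emb.values[n_s:], list(target.cell_ids)))


def annotate_query(source: CellByPeakMatrix, source_labels: LabelTable,
                   target: CellByPeakMatrix, *, route: str = "lsi",
                   lsi_dim: int = 128, sequences=None,
                   embedder_spec: EmbedderSpec | None = None,
                   encoder_cfg: EncoderConfig | None = None,
                   k: int = 15, metric: str = "euclidean",
                   gda_cfg: GDAConfig | None = None, min_cells: int = 1):
    """Full two-stage annotation of an unlabeled query against a reference.

    Returns ``(predictions: LabelTable, probabilities, state)`` where
    probability columns follow the sorted reference class order.
    """
    if list(source_labels.cell_ids) != list(source.cell_ids):
        raise ValueError("source labels must align with source cell_ids")
    cfg = gda_cfg or GDAConfig()
    emb_s, emb_t = joint_cell_embeddings(
        source, target, route, lsi_dim=lsi_dim, sequences=sequences,
        embedder_spec=embedder_spec, encoder_cfg=encoder_cfg,
        min_cells=min_cells, seed=cfg.seed)
    g_s = build_knn_graph(emb_s, k=k, metric=metric)
    g_t = build_knn_graph(emb_t, k=k, metric=metric)
    classes = source_labels.classes
    if cfg.n_classes != len(classes):
        cfg = GDAConfig(**{**cfg.__dict__, "n_classes": len(classes)})
    state = train_gda(g_s, source_labels.label_indices, g_t, cfg)
    labels, probs = annotate(state, g_t, classes)
    return LabelTable(list(target.cell_ids), labels, classes=classes), probs, state


def knn_transfer_baseline(emb_s: CellEmbeddingMatrix, source_labels: LabelTable,
                          emb_t: CellEmbeddingMatrix, n_neighbors: int = 1,
                          metric: str = "euclidean") -> LabelTable:
    """Plain kNN label transfer in embedding space (no domain adaptation)."""
    from scipy.spatial.distance import cdist

    dist = cdist(emb_t.values, emb_s.values, metric=metric)
    labels = []
    src = np.asarray(source_labels.labels, dtype=object)
    if n_neighbors == 1:
        labels = list(src[np.argmin(dist, axis=1)])
    else:
        nn = np.argsort(dist, axis=1, kind="stable")[:, :n_neighbors]
        for row in nn:
            vals, counts = np.unique(src[row], return_counts=True)
            labels.append(vals[np.argmax(counts)])
    return LabelTable(list(emb_t.cell_ids), labels, classes=source_labels.classes)
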