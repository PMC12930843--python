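"""Reproducible simulation studies: transfer accuracy and ablations.

These routines run the full two-stage pipeline on the simulated
cross-platform setting (batch dropout between reference and query) and report
accuracy / macro-F1 for the adversarially aligned model, the same model with
the domain loss disabled, and a plain 1-NN embedding-transfer baseline. They
back both the package's acceptance checks and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from .cell_embedding import EncoderConfig, extract_cell_embeddings, train_encoder
from .domain_adaptation import GDAConfig, annotate, train_gda
from .graph_construction import build_knn_graph
from .io_formats import LabelTable
from .pipeline import joint_cell_embeddings, knn_transfer_baseline
from .sequence_embedding import EmbedderSpec, embed_peaks
from .synthetic_data import SimConfig, ground_truth_report, simulate_pair


def transfer_study_one_seed(seed: int, *, lsi_dim: int = 128, k: int = 15,
                            K: int = 3, epochs: int = 200,
                            sim_overrides: dict | None = None) -> dict:
    """One simulated reference→query transfer at the study conditions.

    Returns metrics for the adversarial model (lambda=1), the lambda=0
    ablation, and the 1-NN embedding-transfer baseline, sharing one LSI
    embedding and one graph pair across the three.
    """
    cfg = SimConfig(seed=seed, **(sim_overrides or {}))
    src, src_lab, tgt, tgt_lab, _, _ = simulate_pair(cfg)
    emb_s, emb_t = joint_cell_embeddings(src, tgt, "lsi", lsi_dim=lsi_dim,
                                         seed=seed)
    g_s = build_knn_graph(emb_s, k=k)
    g_t = build_knn_graph(emb_t, k=k)
    out = {}
    for name, lam in (("da", 1.0), ("no_da", 0.0)):
        gda = GDAConfig(n_classes=src_lab.n_classes, K=K, lam=lam,
                        epochs=epochs, seed=seed)
        state = train_gda(g_s, src_lab.label_indices, g_t, gda)
        labels, _ = annotate(state, g_t, src_lab.classes)
        pred = LabelTable(list(tgt.cell_ids), labels, classes=src_lab.classes)
        out[name] = ground_truth_report(pred, tgt_lab)
    baseline = knn_transfer_baseline(emb_s, src_lab, emb_t)
    out["knn_baseline"] = ground_truth_report(baseline, tgt_lab)
    return out


def run_transfer_study(seeds, **kwargs) -> dict:
    """Run the transfer study over several simulation seeds.

    Returns per-arm metric lists plus their medians.
    """
    runs = [transfer_study_one_seed(s, **kwargs) for s in seeds]
    study = {"seeds": list(seeds)}
    for arm in ("da", "no_da", "knn_baseline"):
        for metric in ("accuracy", "macro_f1"):
            vals = [r[arm][metric] for r in runs]
            study[f"{arm}_{metric}"] = vals
            study[f"{arm}_{metric}_median"] = float(np.median(vals))
    return study


def embedding_separation_one_seed(seed: int, *, embedder_k: int = 4,
                                  embedder_d: int = 64,
                                  hidden_dims=(128, 64), epochs: int = 30,
                                  sim_overrides: dict | None = None) -> dict:
    """Within- versus between-type cosine similarity of Stage-1 embeddings.

    Embeds the motif-bearing peak sequences with the k-mer embedder, trains
    the accessibility predictor on the joint cell set, and compares mean
    cosine similarity of reference-cell embeddings inside and across types.
    """
    cfg = SimConfig(seed=seed, **(sim_overrides or {}))
    src, src_lab, tgt, _, _, seqs = simulate_pair(cfg)
    spec = EmbedderSpec(kind="kmer_projection", k=embedder_k, d=embedder_d,
                        seed=seed)
    enc = EncoderConfig(hidden_dims=list(hidden_dims), epochs=epochs,
                        batch_size=128, seed=seed)
    emb_s, _ = joint_cell_embeddings(src, tgt, "sequence", sequences=seqs,
                                     embedder_spec=spec, encoder_cfg=enc)
    x = emb_s.values / np.linalg.norm(emb_s.values, axis=1, keepdims=True)
    sim = x @ x.T
    lab = np.asarray(src_lab.label_indices)
    same = (lab[:, None] == lab[None, :]) & ~np.eye(len(lab), dtype=bool)
    diff = lab[:, None] != lab[None, :]
    return {"within": float(sim[same].mean()),
            "between": float(sim[diff].mean()),
            "margin": float(sim[same].mean() - sim[diff].mean())}
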