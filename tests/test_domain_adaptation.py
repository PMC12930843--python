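"""Asymmetric weight-shared GCN paths, adversarial alignment, and training."""

import numpy as np
import pytest
import scipy.sparse as sp

import seqalignatac as sa
from seqalignatac import _autograd as ag
from seqalignatac.domain_adaptation import (GDAState, domain_discriminator,
                                            domain_labels, gcn_layer, grl)
from seqalignatac.graph_construction import DomainGraph, normalize_adjacency
from seqalignatac.sequence_embedding import CellEmbeddingMatrix


def _graph(features, edges=frozenset()):
    features = np.asarray(features, dtype=float)
    g = DomainGraph([f"c{i}" for i in range(features.shape[0])], features,
                    set(edges), 1, "euclidean")
    normalize_adjacency(g)
    return g


def _state(input_dim, cfg=None, seed=0):
    cfg = cfg or sa.GDAConfig(hidden1=6, hidden2=4, n_classes=3)
    return GDAState(input_dim, cfg, np.random.default_rng(seed))


# ------------------------------------------------------------------ gcn_layer

def test_gcn_layer_identity_adjacency_is_affine_relu(rng):
    x = rng.standard_normal((4, 3))
    w = rng.standard_normal((3, 2))
    out = gcn_layer(x, sp.eye(4).tocsr(), w, activate=True)
    assert out.data == pytest.approx(np.maximum(x @ w, 0), abs=1e-12)


def test_gcn_layer_two_node_edge_hand_example():
    g = _graph(np.eye(2), {(0, 1), (1, 0)})
    out = gcn_layer(np.eye(2), g.normalized_adjacency, np.eye(2))
    assert out.data == pytest.approx(np.full((2, 2), 0.5), abs=1e-12)


def test_gcn_layer_zero_input_zero_output(rng):
    out = gcn_layer(np.zeros((3, 2)), sp.eye(3).tocsr(),
                    rng.standard_normal((2, 5)), activate=True)
    assert np.array_equal(out.data, np.zeros((3, 5)))


# --------------------------------------------------- source / target forwards

def test_source_path_on_edgeless_graph_is_mlp(rng):
    st = _state(5)
    g = _graph(rng.standard_normal((6, 5)))
    out = sa.source_forward(st, g)
    h = np.maximum(g.features @ st.w1.data, 0)
    z = np.maximum(h @ st.w2.data, 0)
    assert out == pytest.approx(z @ st.w3.data, abs=1e-12)


def test_target_k1_equals_source_on_edgeless_graph(rng):
    st = _state(4)
    g = _graph(rng.standard_normal((5, 4)))
    assert sa.target_forward(st, g, K=1) == pytest.approx(
        sa.source_forward(st, g), abs=1e-8)


def test_target_output_k_independent_on_edgeless_graph(rng):
    st = _state(4)
    g = _graph(rng.standard_normal((5, 4)))
    a = sa.target_forward(st, g, K=1)
    b = sa.target_forward(st, g, K=5)
    assert a == pytest.approx(b, abs=1e-10)


def test_complete_graph_uniform_features_uniform_rows(rng):
    n = 4
    edges = {(i, j) for i in range(n) for j in range(n) if i != j}
    g = _graph(np.ones((n, 3)), edges)
    st = _state(3)
    out = sa.target_forward(st, g, K=2)
    assert out == pytest.approx(np.tile(out[0], (n, 1)), abs=1e-10)


def test_target_k3_matches_explicit_propagation_oracle(rng):
    # 5-node path graph, one-hot features
    edges = set()
    for i in range(4):
        edges |= {(i, i + 1), (i + 1, i)}
    g = _graph(np.eye(5), edges)
    st = _state(5)
    out = sa.target_forward(st, g, K=3)
    a = g.normalized_adjacency.toarray()
    h = np.maximum(a @ np.eye(5) @ st.w1.data, 0)
    z = h @ st.w2.data
    for _ in range(3):
        z = a @ z
    oracle = a @ (np.maximum(z, 0) @ st.w3.data)
    assert out == pytest.approx(oracle, abs=1e-10)


def test_forward_paths_permutation_equivariant(rng):
    st = _state(3)
    x = rng.standard_normal((8, 3))
    emb = CellEmbeddingMatrix(x, [f"c{i}" for i in range(8)])
    g = sa.build_knn_graph(emb, k=2)
    perm = rng.permutation(8)
    inv = np.empty(8, dtype=int)
    inv[perm] = np.arange(8)
    gp = DomainGraph([g.node_ids[i] for i in perm], x[perm],
                     {(inv[i], inv[j]) for i, j in g.edges}, 2, "euclidean")
    normalize_adjacency(gp)
    for fwd in (sa.source_forward, lambda s, gg: sa.target_forward(s, gg, K=3)):
        assert fwd(st, gp) == pytest.approx(fwd(st, g)[perm], abs=1e-10)


def test_weight_sharing_mutation_visible_in_both_paths(rng):
    st = _state(3)
    g = _graph(rng.standard_normal((5, 3)), {(0, 1), (1, 0)})
    s0, t0 = sa.source_forward(st, g), sa.target_forward(st, g, K=2)
    st.w2.data *= 2.0
    assert not np.allclose(sa.source_forward(st, g), s0)
    assert not np.allclose(sa.target_forward(st, g, K=2), t0)


# ----------------------------------------------------------- GRL + losses

def test_grl_forward_identity_and_schedule_binding(rng):
    z = rng.standard_normal((3, 4))
    assert np.array_equal(grl(z, 0.3).data, z)


def test_grl_gamma_zero_detaches_gradient(rng):
    x = ag.Tensor(rng.standard_normal((2, 2)), requires_grad=True)
    ag.bce_with_logits(ag.grl(x, 0.0), np.ones((2, 2))).backward()
    assert np.array_equal(x.grad, np.zeros((2, 2)))


def test_discriminator_zero_weights_uniform_ln2(rng):
    st = _state(3)
    for p in st.discriminator_parameters():
        p.data[:] = 0.0
    z = rng.standard_normal((4, 4))
    d = domain_discriminator(st, z)
    assert np.array_equal(d.data, np.zeros((4, 2)))
    assert sa.domain_loss(d.data[:2], d.data[2:]) == pytest.approx(np.log(2),
                                                                   abs=1e-12)


def test_discriminator_row_permutation_and_shape(rng):
    st = _state(3)
    z = rng.standard_normal((6, 4))
    d = domain_discriminator(st, z).data
    perm = rng.permutation(6)
    assert domain_discriminator(st, z[perm]).data == pytest.approx(d[perm],
                                                                   abs=1e-12)
    assert d.shape == (6, 2)
    with pytest.raises(ValueError, match="width"):
        domain_discriminator(st, z[:, :3])


def test_classification_loss_closed_forms_and_oracle(rng):
    assert sa.classification_loss(np.zeros((3, 4)), [0, 1, 2]) == pytest.approx(
        np.log(4), abs=1e-12)
    confident = np.full((2, 3), 0.0)
    confident[0, 1] = confident[1, 2] = 20.0
    assert sa.classification_loss(confident, [1, 2]) < 1e-7
    z = rng.standard_normal((6, 3)) * 2
    y = rng.integers(0, 3, size=6)
    p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
    oracle = -np.log(p[np.arange(6), y]).mean()
    assert sa.classification_loss(z, y) == pytest.approx(oracle, abs=1e-10)
    with pytest.raises(ValueError, match="range"):
        sa.classification_loss(np.zeros((2, 2)), [0, 2])


def test_domain_labels_layout_and_loss_limits():
    assert domain_labels(2, 3).tolist() == [0, 0, 1, 1, 1]
    sep_s = np.tile([20.0, -20.0], (2, 1))
    sep_t = np.tile([-20.0, 20.0], (3, 1))
    assert sa.domain_loss(sep_s, sep_t) < 1e-7
    assert sa.domain_loss(np.zeros((2, 2)), np.zeros((3, 2))) == pytest.approx(
        np.log(2), abs=1e-12)


def test_grl_schedule_endpoints_and_monotonicity():
    E = 200
    assert sa.grl_schedule(0, E) == 0.0
    assert sa.grl_schedule(E, E) == pytest.approx(2 / (1 + np.exp(-10)) - 1,
                                                  abs=1e-12)
    assert sa.grl_schedule(E // 2, E) == pytest.approx(2 / (1 + np.exp(-5)) - 1,
                                                       abs=1e-12)
    vals = [sa.grl_schedule(e, E) for e in range(E + 1)]
    assert all(b > a for a, b in zip(vals, vals[1:]))
    assert 0 <= min(vals) and max(vals) < 1


def test_total_loss_arithmetic():
    assert sa.total_loss(np.log(4), np.log(2), 1.0) == pytest.approx(np.log(8),
                                                                     abs=1e-12)
    assert sa.total_loss(1.5, 99.0, 0.0) == 1.5
    assert sa.total_loss(1.0, 2.0, 3.0) == pytest.approx(7.0)


# ------------------------------------------------------------------ training

def test_adversarial_gradients_oppose(rng):
    """The GRL makes encoder and discriminator push L_dom in opposite directions."""
    st = _state(3, sa.GDAConfig(hidden1=6, hidden2=4, n_classes=2, seed=1))
    g_s = _graph(rng.standard_normal((10, 3)) + 2, {(0, 1), (1, 0)})
    g_t = _graph(rng.standard_normal((10, 3)) - 2, {(2, 3), (3, 2)})
    from seqalignatac.domain_adaptation import _source_graph, _target_graph

    def dom_loss_value():
        _, z_s = _source_graph(st, g_s)
        _, z_t = _target_graph(st, g_t, 2)
        d = domain_discriminator(st, ag.concat([z_s, z_t]))
        return float(ag.softmax_cross_entropy(d, domain_labels(10, 10)).data)

    _, z_s = _source_graph(st, g_s)
    _, z_t = _target_graph(st, g_t, 2)
    d = domain_discriminator(st, ag.grl(ag.concat([z_s, z_t]), 1.0))
    loss = ag.softmax_cross_entropy(d, domain_labels(10, 10))
    for p in st.parameters():
        p.grad = None
    loss.backward()
    base = dom_loss_value()
    backup = [p.data.copy() for p in st.parameters()]
    lr = 1e-4
    # discriminator-only step along the gradient decreases L_dom
    for p in st.discriminator_parameters():
        p.data -= lr * p.grad
    assert dom_loss_value() < base
    for p, b in zip(st.parameters(), backup):
        p.data[:] = b
    # encoder-only step (gradients flow through the GRL) increases L_dom
    for p in st.encoder_parameters():
        if p.grad is not None:
            p.data -= lr * p.grad
    assert dom_loss_value() > base


def test_k_propagation_smooths_monotonically(rng):
    emb = CellEmbeddingMatrix(rng.standard_normal((30, 4)),
                              [f"c{i}" for i in range(30)])
    g = sa.build_knn_graph(emb, k=3)
    st = _state(4)
    variances = []
    for K in range(1, 6):
        _, z = sa.target_forward(st, g, K=K, return_z=True)
        variances.append(z.var(axis=0).sum())
    assert all(b <= a + 1e-12 for a, b in zip(variances, variances[1:]))


def test_train_lambda0_identical_graphs_k0_predictions_match(rng):
    emb = CellEmbeddingMatrix(rng.standard_normal((20, 4)),
                              [f"c{i}" for i in range(20)])
    g = sa.build_knn_graph(emb, k=3)
    labels = rng.integers(0, 2, size=20)
    cfg = sa.GDAConfig(hidden1=8, hidden2=4, n_classes=2, K=0, lam=0.0,
                       epochs=20, seed=0)
    st = sa.train_gda(g, labels, g, cfg)
    assert sa.target_forward(st, g, K=0) == pytest.approx(
        sa.source_forward(st, g), abs=1e-10)


def test_train_rejects_too_few_classes(rng):
    emb = CellEmbeddingMatrix(rng.standard_normal((10, 3)),
                              [f"c{i}" for i in range(10)])
    g = sa.build_knn_graph(emb, k=2)
    cfg = sa.GDAConfig(n_classes=2, epochs=1)
    with pytest.raises(ValueError, match="n_classes"):
        sa.train_gda(g, np.arange(10) % 3, g, cfg)


def test_training_log_and_determinism(rng):
    emb = CellEmbeddingMatrix(rng.standard_normal((15, 3)),
                              [f"c{i}" for i in range(15)])
    g = sa.build_knn_graph(emb, k=2)
    labels = np.arange(15) % 2
    cfg = sa.GDAConfig(hidden1=6, hidden2=4, n_classes=2, epochs=5, seed=3)
    a = sa.train_gda(g, labels, g, cfg)
    b = sa.train_gda(g, labels, g, cfg)
    assert [r["total"] for r in a.log] == [r["total"] for r in b.log]
    assert [r["gamma"] for r in a.log] == [sa.grl_schedule(e, 5) for e in range(5)]


def test_annotate_tie_break_and_probabilities(rng):
    emb = CellEmbeddingMatrix(rng.standard_normal((12, 3)),
                              [f"c{i}" for i in range(12)])
    g = sa.build_knn_graph(emb, k=2)
    cfg = sa.GDAConfig(hidden1=6, hidden2=4, n_classes=3, epochs=3, seed=0)
    st = sa.train_gda(g, rng.integers(0, 3, size=12), g, cfg)
    labels, probs = sa.annotate(st, g, ["A", "B", "C"])
    assert probs.shape == (12, 3)
    assert probs.sum(axis=1) == pytest.approx(np.ones(12), abs=1e-6)
    assert len(labels) == 12
    with pytest.raises(ValueError, match="class names"):
        sa.annotate(st, g, ["A", "B"])
    # explicit tie: equal top logits resolve to the lowest class index
    row = np.array([[2.0, 2.0, -1.0]])
    assert int(np.argmax(row, axis=1)[0]) == 0
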