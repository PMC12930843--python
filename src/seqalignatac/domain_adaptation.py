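"""Stage 2: graph domain adaptation for label transfer.

A weight-shared, asymmetric-depth pair of GCN paths classifies cells on the
labeled source graph and the unlabeled target graph. The source path is
shallow (propagate, transform, propagate) to avoid over-smoothing under full
supervision; the target path inserts K extra propagation steps in the middle
layer to enlarge the receptive field where no labels exist. Both paths read
the same three weight matrices. A domain discriminator behind a gradient
reversal layer (GRL) adversarially aligns the intermediate representations of
the two domains; its weight follows a sigmoidal schedule over training
progress so that adversarial pressure ramps up as the classifier stabilizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from . import _autograd as ag
from .graph_construction import DomainGraph


@dataclass
class GDAConfig:
    hidden1: int = 128
    hidden2: int = 64
    n_classes: int = 2
    K: int = 3
    lam: float = 1.0
    epochs: int = 200
    learning_rate: float = 1e-3
    discriminator_hidden: int = 32
    seed: int = 0
    grl_coeff: float | None = None  # override; None binds GRL to the schedule

    def __post_init__(self):
        if min(self.hidden1, self.hidden2, self.n_classes,
               self.discriminator_hidden, self.epochs) < 1:
            raise ValueError("widths, n_classes and epochs must be positive")
        if self.K < 0:
            raise ValueError("K must be >= 0 (0 is the source-equivalence test mode)")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


class GDAState:
    """Shared GCN weights, classifier head, and discriminator parameters.

    ``w1``, ``w2``, ``w3`` are single tensors read by BOTH forward paths:
    mutating one mutates the other path's computation by construction.
    """

    def __init__(self, input_dim: int, cfg: GDAConfig, rng: np.random.Generator):
        self.cfg = cfg

        def he(fan_in, fan_out):
            return ag.Tensor(rng.standard_normal((fan_in, fan_out))
                             * np.sqrt(2.0 / fan_in), requires_grad=True)

        self.w1 = he(input_dim, cfg.hidden1)
        self.w2 = he(cfg.hidden1, cfg.hidden2)
        self.w3 = he(cfg.hidden2, cfg.n_classes)
        self.disc_w1 = he(cfg.hidden2, cfg.discriminator_hidden)
        self.disc_b1 = ag.Tensor(np.zeros(cfg.discriminator_hidden), requires_grad=True)
        self.disc_w2 = he(cfg.discriminator_hidden, 2)
        self.disc_b2 = ag.Tensor(np.zeros(2), requires_grad=True)
        self.log: list[dict] = []

    def encoder_parameters(self):
        return [self.w1, self.w2, self.w3]

    def discriminator_parameters(self):
        return [self.disc_w1, self.disc_b1, self.disc_w2, self.disc_b2]

    def parameters(self):
        return self.encoder_parameters() + self.discriminator_parameters()


def gcn_layer(x, adjacency, w, activate: bool = False):
    """One graph convolution: adjacency @ (x @ w), optional ReLU. Bias-free."""
    xt = x if isinstance(x, ag.Tensor) else ag.Tensor(np.asarray(x, dtype=np.float64))
    wt = w if isinstance(w, ag.Tensor) else ag.Tensor(np.asarray(w, dtype=np.float64))
    out = ag.spmm(adjacency, ag.matmul(xt, wt))
    if activate:
        out = ag.relu(out)
    return out


def _check_graph(g: DomainGraph, state: GDAState):
    if g.normalized_adjacency is None:
        raise ValueError("graph adjacency not normalized")
    if g.features.shape[1] != state.w1.data.shape[0]:
        raise ValueError(
            f"feature dim {g.features.shape[1]} != W1 fan-in {state.w1.data.shape[0]}")


def _source_graph(state: GDAState, g: DomainGraph):
    """Shallow source path; returns (logits, Z) autodiff tensors."""
    _check_graph(g, state)
    a = g.normalized_adjacency
    h = gcn_layer(g.features, a, state.w1, activate=True)
    z = ag.relu(ag.matmul(h, state.w2))  # depth-zero transformation: no propagation
    logits = gcn_layer(z, a, state.w3)
    return logits, z


def _target_graph(state: GDAState, g: DomainGraph, K: int):
    """Deep target path: one W2 transformation, then K propagation steps."""
    _check_graph(g, state)
    a = g.normalized_adjacency
    h = gcn_layer(g.features, a, state.w1, activate=True)
    z = ag.matmul(h, state.w2)
    for _ in range(K):
        z = ag.spmm(a, z)
    z = ag.relu(z)
    logits = gcn_layer(z, a, state.w3)
    return logits, z


def source_forward(state: GDAState, g: DomainGraph, return_z: bool = False):
    logits, z = _source_graph(state, g)
    return (logits.data, z.data) if return_z else logits.data


def target_forward(state: GDAState, g: DomainGraph, K: int | None = None,
                   return_z: bool = False):
    K = state.cfg.K if K is None else K
    if K < 0:
        raise ValueError("K must be >= 0")
    logits, z = _target_graph(state, g, K)
    return (logits.data, z.data) if return_z else logits.data


def grl(z, gamma: float):
    """Gradient reversal: identity forward, gradient scaled by -gamma backward."""
    zt = z if isinstance(z, ag.Tensor) else ag.Tensor(np.asarray(z, dtype=np.float64))
    return ag.grl(zt, gamma)


def domain_discriminator(state: GDAState, z):
    """Two-layer perceptron scoring domain membership (0 source, 1 target)."""
    zt = z if isinstance(z, ag.Tensor) else ag.Tensor(np.asarray(z, dtype=np.float64))
    if zt.data.shape[1] != state.cfg.hidden2:
        raise ValueError(f"discriminator input width {zt.data.shape[1]} "
                         f"!= hidden2 {state.cfg.hidden2}")
    h = ag.relu(ag.matmul(zt, state.disc_w1) + state.disc_b1)
    return ag.matmul(h, state.disc_w2) + state.disc_b2


def classification_loss(logits, labels) -> float:
    """Mean negative log softmax probability of the true class (NLL loss)."""
    arr = logits.data if isinstance(logits, ag.Tensor) else np.asarray(logits, float)
    return float(ag.softmax_cross_entropy(ag.Tensor(arr), np.asarray(labels)).data)


def domain_loss(d_source, d_target) -> float:
    """Cross-entropy of concatenated domain logits against [0]*Ns + [1]*Nt."""
    ds = d_source.data if isinstance(d_source, ag.Tensor) else np.asarray(d_source, float)
    dt = d_target.data if isinstance(d_target, ag.Tensor) else np.asarray(d_target, float)
    d = np.concatenate([ds, dt], axis=0)
    y = domain_labels(ds.shape[0], dt.shape[0])
    return float(ag.softmax_cross_entropy(ag.Tensor(d), y).data)


def domain_labels(n_source: int, n_target: int) -> np.ndarray:
    return np.concatenate([np.zeros(n_source, dtype=np.int64),
                           np.ones(n_target, dtype=np.int64)])


def grl_schedule(e: int, E: int) -> float:
    """Adversarial weight gamma = 2 / (1 + exp(-10 e/E)) - 1, in [0, 1)."""
    if not 0 <= e <= E or E < 1:
        raise ValueError("requires 0 <= e <= E and E >= 1")
    p = e / E
    return 2.0 / (1.0 + np.exp(-10.0 * p)) - 1.0


def total_loss(l_cls: float, l_dom: float, lam: float) -> float:
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    return l_cls + lam * l_dom


def train_gda(g_s: DomainGraph, source_labels: np.ndarray, g_t: DomainGraph,
              cfg: GDAConfig) -> GDAState:
    """Adversarial training loop over full graphs.

    Each epoch runs both forward paths, computes the source classification
    loss plus the scheduled GRL domain loss, and takes one Adam step on all
    shared and discriminator parameters. Target labels are never consumed.
    """
    source_labels = np.asarray(source_labels, dtype=np.int64)
    if source_labels.shape[0] != g_s.n_nodes:
        raise ValueError("labels must cover every source node")
    n_distinct = len(np.unique(source_labels))
    if cfg.n_classes < n_distinct:
        raise ValueError(f"n_classes={cfg.n_classes} < {n_distinct} distinct labels")
    rng = np.random.default_rng(cfg.seed)
    state = GDAState(g_s.features.shape[1], cfg, rng)
    opt = ag.Adam(state.parameters(), lr=cfg.learning_rate)
    dom_y = domain_labels(g_s.n_nodes, g_t.n_nodes)
    for e in range(cfg.epochs):
        gamma = grl_schedule(e, cfg.epochs) if cfg.grl_coeff is None else cfg.grl_coeff
        s_logits, z_s = _source_graph(state, g_s)
        _, z_t = _target_graph(state, g_t, cfg.K)
        l_cls = ag.softmax_cross_entropy(s_logits, source_labels)
        d = domain_discriminator(state, ag.grl(ag.concat([z_s, z_t]), gamma))
        l_dom = ag.softmax_cross_entropy(d, dom_y)
        loss = l_cls + cfg.lam * l_dom
        opt.zero_grad()
        loss.backward()
        opt.step()
        state.log.append({"epoch": e, "L_cls": float(l_cls.data),
                          "L_dom": float(l_dom.data), "gamma": float(gamma),
                          "total": float(loss.data)})
    return state


def annotate(state: GDAState, g_t: DomainGraph, class_names):
    """Predict target-cell labels with softmax probabilities.

    Ties resolve to the lowest class index. Returns (labels, probabilities).
    """
    class_names = list(class_names)
    if len(class_names) != state.cfg.n_classes:
        raise ValueError(f"expected {state.cfg.n_classes} class names, "
                         f"got {len(class_names)}")
    logits = target_forward(state, g_t)
    z = logits - logits.max(axis=1, keepdims=True)
    probs = np.exp(z)
    probs /= probs.sum(axis=1, keepdims=True)
    pred_idx = np.argmax(logits, axis=1)  # argmax returns the first (lowest) index
    return [class_names[i] for i in pred_idx], probs
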