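"""Stage 1: learn cell embeddings from peak-sequence embeddings.

A feedforward network maps each peak's sequence embedding to that peak's
predicted accessibility across all C cells (one output unit per cell), trained
with binary cross-entropy against the binarized cell-by-peak matrix. Training
samples are peaks. After training, column c of the output-layer weight matrix
is the embedding of cell c: it is the projection that reconstructs cell c's
accessibility profile from peak-level latent features, i.e. a cell-specific
regulatory signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _autograd as ag
from .sequence_embedding import CellEmbeddingMatrix, PeakEmbeddingMatrix
from .io_formats import CellByPeakMatrix

_ACTIVATIONS = {"relu": ag.relu}


@dataclass
class EncoderConfig:
    hidden_dims: list[int] = field(default_factory=lambda: [512, 128])
    activation: str = "relu"
    epochs: int = 50
    batch_size: int = 128
    learning_rate: float = 1e-3
    seed: int = 0
    batch_norm: bool = True  # identity-BN test hook when False

    def __post_init__(self):
        if len(self.hidden_dims) < 1 or any(h < 1 for h in self.hidden_dims):
            raise ValueError("hidden_dims must be >= 1 positive integers")
        if self.activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")


class EncoderState:
    """Parameters of the trained accessibility predictor.

    ``weights[l]``/``biases[l]`` are the affine parameters of layer l+1; the
    last entry is the output layer whose weight has shape D x C. Hidden layers
    carry batch-norm parameters and running statistics.
    """

    def __init__(self, input_dim: int, hidden_dims: list[int], n_cells: int,
                 cfg: EncoderConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.n_cells = n_cells
        dims = [input_dim] + list(hidden_dims) + [n_cells]
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = rng.standard_normal((fan_in, fan_out)) * np.sqrt(2.0 / fan_in)
            self.weights.append(ag.Tensor(w, requires_grad=True))
            self.biases.append(ag.Tensor(np.zeros(fan_out), requires_grad=True))
        self.bn_gamma = [ag.Tensor(np.ones(h), requires_grad=True) for h in hidden_dims]
        self.bn_beta = [ag.Tensor(np.zeros(h), requires_grad=True) for h in hidden_dims]
        self.bn_mean = [np.zeros(h) for h in hidden_dims]
        self.bn_var = [np.ones(h) for h in hidden_dims]
        self.loss_history: list[float] = []

    @property
    def n_hidden_layers(self):
        return len(self.bn_gamma)

    @property
    def embedding_dim(self):
        return self.weights[-1].data.shape[0]

    def parameters(self):
        params = self.weights + self.biases
        if self.cfg.batch_norm:
            params = params + self.bn_gamma + self.bn_beta
        return params


def _forward_graph(state: EncoderState, x: ag.Tensor, train_mode: bool):
    """Autodiff forward pass; returns (logits, last hidden activation)."""
    act = _ACTIVATIONS[state.cfg.activation]
    h = x
    for l in range(state.n_hidden_layers):
        h = ag.matmul(h, state.weights[l]) + state.biases[l]
        if state.cfg.batch_norm:
            h = ag.batch_norm(h, state.bn_gamma[l], state.bn_beta[l],
                              state.bn_mean[l], state.bn_var[l], training=train_mode)
        h = act(h)
    logits = ag.matmul(h, state.weights[-1]) + state.biases[-1]
    return logits, h


def encoder_forward(state: EncoderState, X, train_mode: bool = False,
                    return_hidden: bool = False):
    """Predict per-cell accessibility logits (N peaks x C cells).

    ``train_mode`` selects batch versus running batch-norm statistics.
    """
    x = X.values if isinstance(X, PeakEmbeddingMatrix) else np.asarray(X, dtype=np.float64)
    if x.shape[1] != state.weights[0].data.shape[0]:
        raise ValueError(
            f"input dim {x.shape[1]} != layer-1 fan-in {state.weights[0].data.shape[0]}")
    logits, hidden = _forward_graph(state, ag.Tensor(x), train_mode)
    if return_hidden:
        return logits.data, hidden.data
    return logits.data


def bce_loss(logits, targets) -> float:
    """Mean binary cross-entropy of sigmoid(logits) against binary targets."""
    targets = np.asarray(targets, dtype=np.float64)
    if not np.isin(targets, (0.0, 1.0)).all():
        raise ValueError("targets must be binary")
    return float(ag.bce_with_logits(ag.Tensor(np.asarray(logits, dtype=np.float64)),
                                    targets).data)


def train_encoder(X: PeakEmbeddingMatrix, m: CellByPeakMatrix,
                  cfg: EncoderConfig) -> EncoderState:
    """Fit the accessibility predictor by minibatch Adam over peaks."""
    if list(X.peak_ids) != list(m.peak_ids):
        raise ValueError("peak ids of embedding matrix and cell-by-peak matrix differ")
    targets = np.asarray((m.values > 0).todense()).T.astype(np.float64)  # N x C
    n_peaks = X.values.shape[0]
    rng = np.random.default_rng(cfg.seed)
    state = EncoderState(X.values.shape[1], cfg.hidden_dims, m.n_cells, cfg, rng)
    opt = ag.Adam(state.parameters(), lr=cfg.learning_rate)
    for _ in range(cfg.epochs):
        order = rng.permutation(n_peaks)
        epoch_loss, n_batches = 0.0, 0
        for lo in range(0, n_peaks, cfg.batch_size):
            idx = order[lo:lo + cfg.batch_size]
            logits, _ = _forward_graph(state, ag.Tensor(X.values[idx]), train_mode=True)
            loss = ag.bce_with_logits(logits, targets[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        state.loss_history.append(epoch_loss / n_batches)
    return state


def extract_cell_embeddings(state: EncoderState, cell_ids) -> CellEmbeddingMatrix:
    """Cell embeddings = columns of the output-layer weight matrix (no bias)."""
    cell_ids = list(cell_ids)
    if len(cell_ids) != state.n_cells:
        raise ValueError(f"expected {state.n_cells} cell_ids, got {len(cell_ids)}")
    return CellEmbeddingMatrix(state.weights[-1].data.T.copy(), cell_ids)


def save_checkpoint(state: EncoderState, path):
    """Serialize config plus all parameters and running statistics."""
    arrays = {}
    for i, (w, b) in enumerate(zip(state.weights, state.biases)):
        arrays[f"w{i}"] = w.data
        arrays[f"b{i}"] = b.data
    for i in range(state.n_hidden_layers):
        arrays[f"bn_gamma{i}"] = state.bn_gamma[i].data
        arrays[f"bn_beta{i}"] = state.bn_beta[i].data
        arrays[f"bn_mean{i}"] = state.bn_mean[i]
        arrays[f"bn_var{i}"] = state.bn_var[i]
    cfg = state.cfg
    np.savez(path, n_layers=len(state.weights), n_cells=state.n_cells,
             hidden_dims=np.array(cfg.hidden_dims), epochs=cfg.epochs,
             batch_size=cfg.batch_size, learning_rate=cfg.learning_rate,
             seed=cfg.seed, batch_norm=int(cfg.batch_norm),
             loss_history=np.array(state.loss_history), **arrays)


def load_checkpoint(path) -> EncoderState:
    z = np.load(path)
    cfg = EncoderConfig(hidden_dims=[int(h) for h in z["hidden_dims"]],
                        epochs=int(z["epochs"]), batch_size=int(z["batch_size"]),
                        learning_rate=float(z["learning_rate"]), seed=int(z["seed"]),
                        batch_norm=bool(int(z["batch_norm"])))
    state = EncoderState(int(z["w0"].shape[0]), cfg.hidden_dims, int(z["n_cells"]),
                         cfg, np.random.default_rng(0))
    for i in range(int(z["n_layers"])):
        state.weights[i].data = z[f"w{i}"]
        state.biases[i].data = z[f"b{i}"]
    for i in range(state.n_hidden_layers):
        state.bn_gamma[i].data = z[f"bn_gamma{i}"]
        state.bn_beta[i].data = z[f"bn_beta{i}"]
        state.bn_mean[i][:] = z[f"bn_mean{i}"]
        state.bn_var[i][:] = z[f"bn_var{i}"]
    state.loss_history = [float(v) for v in z["loss_history"]]
    return state
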