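"""The sequence-to-activity model and its forward/backward computations.

Architecture: a single convolutional layer (d filters of shape m x 4, no
bias, valid padding, stride 1, forward strand only) -> ELU -> global max
pooling over positions -> fully connected layer (d inputs, p outputs) with
bias.  Each of the d filters is interpretable post hoc as one sequence
motif; the global max pool makes the pooled activation of a filter the best
match score of its motif anywhere in the sequence, and the linear readout
weights that score into a predicted activity per pool.

The model is small enough that forward and analytic gradients are
implemented directly on NumPy arrays (im2col + BLAS matmul); this keeps the
max-pool argmax — needed deterministically by motif extraction, with ties
broken at the lowest position — fully under our control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

FC_BIAS_INIT = 1e-5


@dataclass
class ModelConfig:
    d: int = 600   # number of convolutional filters (candidate motifs)
    m: int = 12    # filter width in nucleotides
    p: int = 1     # number of output pools
    L: int = 1000  # input sequence length

    def __post_init__(self) -> None:
        if self.m > self.L:
            raise ValueError(f"filter width m={self.m} exceeds sequence length L={self.L}")
        if self.d < 1 or self.p < 1:
            raise ValueError("d and p must be >= 1")


@dataclass
class ModelParams:
    """conv_filters (d, m, 4); fc_weights (d, p); fc_bias (p,)."""

    conv_filters: np.ndarray
    fc_weights: np.ndarray
    fc_bias: np.ndarray

    def __post_init__(self) -> None:
        d, m, a = self.conv_filters.shape
        if a != 4:
            raise ValueError("conv filters must have 4 channels (A,C,G,T)")
        if self.fc_weights.shape != (d, self.fc_bias.shape[0]):
            raise ValueError("fc_weights shape inconsistent with conv_filters / fc_bias")
        for arr in (self.conv_filters, self.fc_weights, self.fc_bias):
            if not np.all(np.isfinite(arr)):
                raise ValueError("model parameters must be finite")

    @property
    def d(self) -> int:
        return self.conv_filters.shape[0]

    @property
    def m(self) -> int:
        return self.conv_filters.shape[1]

    @property
    def p(self) -> int:
        return self.fc_bias.shape[0]

    def copy(self) -> "ModelParams":
        return ModelParams(self.conv_filters.copy(), self.fc_weights.copy(), self.fc_bias.copy())


def init_params(config: ModelConfig, sigma_motifs: float, sigma_net: float,
                rng: np.random.Generator) -> ModelParams:
    """Gaussian filter/readout init; fc biases start at a small constant.

    Conv weights ~ N(0, sigma_motifs^2), readout weights ~ N(0, sigma_net^2),
    fc_bias = 1e-5.  Near-zero filters let the optimizer grow only the motifs
    the data supports.
    """
    if sigma_motifs <= 0 or sigma_net <= 0:
        raise ValueError("sigmas must be positive")
    conv = rng.normal(0.0, sigma_motifs, size=(config.d, config.m, 4))
    fc_w = rng.normal(0.0, sigma_net, size=(config.d, config.p))
    fc_b = np.full(config.p, FC_BIAS_INIT)
    return ModelParams(conv.astype(np.float64), fc_w.astype(np.float64), fc_b.astype(np.float64))


def elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.minimum(x, 0.0)))


def im2col(onehot: np.ndarray, m: int) -> np.ndarray:
    """Unfold (n, 4, L) one-hot sequences into (n, L-m+1, 4*m) windows.

    Precomputed once per sequence set; every conv pass is then a single
    matmul against the flattened filters.
    """
    n, four, L = onehot.shape
    windows = np.lib.stride_tricks.sliding_window_view(onehot, m, axis=2)  # (n, 4, P, m)
    return np.ascontiguousarray(windows.transpose(0, 2, 3, 1).reshape(n, L - m + 1, m * four))


def _flat_filters(params: ModelParams) -> np.ndarray:
    # (d, m, 4) -> (m*4, d), matching im2col's (m, 4) window flattening
    return params.conv_filters.reshape(params.d, -1).T


def conv_activations(params: ModelParams, onehot: np.ndarray, cols: np.ndarray | None = None,
                     return_argmax: bool = False):
    """Post-ELU, max-pooled activations a_ik for each sequence k and filter i.

    Returns (n, d) activations, and optionally the (n, d) argmax window
    positions (ties resolved to the lowest position by ``argmax``).
    """
    if cols is None:
        cols = im2col(onehot, params.m)
    z = cols @ _flat_filters(params)          # (n, P, d) pre-activations
    zmax = z.max(axis=1)                      # ELU is monotone: argmax commutes
    act = elu(zmax)
    if return_argmax:
        return act, z.argmax(axis=1)
    return act


def forward(params: ModelParams, onehot: np.ndarray, cols: np.ndarray | None = None):
    """Full forward pass.

    Returns ``(predictions, activations)``: predictions are (n, p), the
    pooled post-ELU activations are (n, d).
    """
    act = conv_activations(params, onehot, cols=cols)
    pred = act @ params.fc_weights + params.fc_bias
    return pred, act


def mse_loss(pred: np.ndarray, target: np.ndarray) -> float:
    """Mean of squared differences over all entries."""
    pred = np.asarray(pred)
    target = np.asarray(target)
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch {pred.shape} vs {target.shape}")
    return float(np.mean((pred - target) ** 2))


def loss_and_grads(params: ModelParams, cols: np.ndarray, target: np.ndarray):
    """MSE loss and its gradients w.r.t. all parameters.

    ``cols`` is the im2col view of the batch.  Gradient routing through the
    global max pool sends each filter's gradient to its argmax window only;
    the ELU derivative is 1 for positive pre-activations and elu(z)+1
    otherwise.
    """
    n = cols.shape[0]
    z = cols @ _flat_filters(params)          # (n, P, d)
    idx = z.argmax(axis=1)                    # (n, d)
    zmax = np.take_along_axis(z, idx[:, None, :], axis=1)[:, 0, :]
    act = elu(zmax)                           # (n, d)
    pred = act @ params.fc_weights + params.fc_bias
    resid = pred - target                     # (n, p)
    loss = float(np.mean(resid ** 2))

    g_pred = (2.0 / resid.size) * resid
    g_fc_w = act.T @ g_pred                   # (d, p)
    g_fc_b = g_pred.sum(axis=0)               # (p,)
    g_act = g_pred @ params.fc_weights.T      # (n, d)
    g_z = g_act * np.where(zmax > 0, 1.0, act + 1.0)
    # gather the argmax windows: (n, d, m*4)
    win = np.take_along_axis(cols, idx[:, :, None], axis=1)
    g_conv = np.einsum("nd,ndf->df", g_z, win).reshape(params.conv_filters.shape)
    return loss, {"conv_filters": g_conv, "fc_weights": g_fc_w, "fc_bias": g_fc_b}


# ---------------------------------------------------------------------------
# Checkpoints
# ---------------------------------------------------------------------------

@dataclass
class Checkpoint:
    """A trained fold model plus the split and metrics needed downstream."""

    params: ModelParams
    config: ModelConfig
    train_ids: np.ndarray
    val_ids: np.ndarray
    test_ids: np.ndarray
    best_val_mse: float
    history: list = field(default_factory=list)
    hyperparams: dict = field(default_factory=dict)

    def save(self, path) -> None:
        np.savez(
            path,
            conv_filters=self.params.conv_filters,
            fc_weights=self.params.fc_weights,
            fc_bias=self.params.fc_bias,
            config=np.array([self.config.d, self.config.m, self.config.p, self.config.L]),
            train_ids=self.train_ids,
            val_ids=self.val_ids,
            test_ids=self.test_ids,
            best_val_mse=np.array(self.best_val_mse),
            history=np.array(self.history, dtype=float),
            hyper_keys=np.array(list(self.hyperparams.keys())),
            hyper_vals=np.array([float(v) for v in self.hyperparams.values()]),
        )

    @classmethod
    def load(cls, path) -> "Checkpoint":
        with np.load(path, allow_pickle=False) as z:
            d, m, p, L = (int(v) for v in z["config"])
            return cls(
                params=ModelParams(z["conv_filters"], z["fc_weights"], z["fc_bias"]),
                config=ModelConfig(d=d, m=m, p=p, L=L),
                train_ids=z["train_ids"],
                val_ids=z["val_ids"],
                test_ids=z["test_ids"],
                best_val_mse=float(z["best_val_mse"]),
                history=z["history"].tolist(),
                hyperparams=dict(zip(z["hyper_keys"].tolist(), z["hyper_vals"].tolist())),
            )
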