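"""Cross-validated training: fold plans, hyperparameter search, Adam fitting.

The data are split into K outer folds; each fold's held-out 10% is the outer
test set and the remaining "inner" set is split 80/20 into training and
validation.  Hyperparameters (learning rate, init scales, batch size) are
drawn from log-uniform/categorical priors and winnowed by synchronous
successive halving; the winning configuration trains the fold's final model
with patience-1 early stopping, and parameters from the best validation
epoch are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from scregmotif.data_io import SequenceSet
from scregmotif.network import (
    Checkpoint,
    ModelConfig,
    ModelParams,
    forward,
    im2col,
    init_params,
    loss_and_grads,
    mse_loss,
)
from scregmotif.pooling import PooledDataset

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Cross-validation plan
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """K outer folds; each holds disjoint test/train/val index arrays."""

    folds: list[dict]  # keys: outer_test, inner_train, inner_val
    rng_seed: int

    @property
    def K(self) -> int:
        return len(self.folds)


def make_cv_plan(n_seqs: int, K: int, rng: np.random.Generator, rng_seed: int = 0) -> CVPlan:
    """Random K-fold partition; each fold's remainder splits 80/20 train/val."""
    if n_seqs < K:
        raise ValueError(f"n_seqs={n_seqs} smaller than K={K}")
    order = rng.permutation(n_seqs)
    outer = np.array_split(order, K)
    folds = []
    for k in range(K):
        test = np.sort(outer[k])
        inner = np.concatenate([outer[j] for j in range(K) if j != k])
        inner = rng.permutation(inner)
        n_val = int(round(0.2 * len(inner)))
        folds.append({
            "outer_test": test,
            "inner_train": np.sort(inner[n_val:]),
            "inner_val": np.sort(inner[:n_val]),
        })
    return CVPlan(folds=folds, rng_seed=rng_seed)


# ---------------------------------------------------------------------------
# Hyperparameter priors
# ---------------------------------------------------------------------------

@dataclass
class HyperPriors:
    lr: tuple[float, float] = (5e-4, 5e-2)
    sigma_motifs: tuple[float, float] = (1e-7, 1e-3)
    sigma_net: tuple[float, float] = (1e-5, 1e-2)
    batch_sizes: tuple[int, ...] = (64, 128, 256, 512)
    epochs: int = 40
    num_calibrations: int = 100

    def __post_init__(self) -> None:
        for lo, hi in (self.lr, self.sigma_motifs, self.sigma_net):
            if not 0 < lo < hi:
                raise ValueError("prior intervals need 0 < lo < hi")


def sample_hyperparams(priors: HyperPriors, rng: np.random.Generator) -> dict:
    """One draw: log-uniform for continuous values, uniform over batch sizes."""

    def logu(lo: float, hi: float) -> float:
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return {
        "lr": logu(*priors.lr),
        "sigma_motifs": logu(*priors.sigma_motifs),
        "sigma_net": logu(*priors.sigma_net),
        "batch_size": int(rng.choice(priors.batch_sizes)),
    }


# ---------------------------------------------------------------------------
# Adam optimizer
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, params: ModelParams, lr: float, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in _param_dict(params).items()}
        self.v = {k: np.zeros_like(v) for k, v in _param_dict(params).items()}

    def step(self, params: ModelParams, grads: dict) -> None:
        self.t += 1
        pd_ = _param_dict(params)
        for key, g in grads.items():
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            m_hat = self.m[key] / (1 - self.b1 ** self.t)
            v_hat = self.v[key] / (1 - self.b2 ** self.t)
            pd_[key] -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)


def _param_dict(params: ModelParams) -> dict:
    return {"conv_filters": params.conv_filters, "fc_weights": params.fc_weights,
            "fc_bias": params.fc_bias}


# ---------------------------------------------------------------------------
# Single-fold training
# ---------------------------------------------------------------------------

def train_model(cols: np.ndarray, targets: np.ndarray, fold: dict, model_config: ModelConfig,
                hyperparams: dict, epochs: int, rng: np.random.Generator,
                patience: int | None = 1) -> Checkpoint:
    """Fit one fold with Adam on MSE; keep parameters from the best val epoch.

    ``cols`` is the im2col unfolding of the full sequence set; ``targets``
    is the (n_seqs, p) pooled matrix aligned row-for-row.  With
    ``patience=1`` training stops at the first epoch whose validation MSE
    fails to improve on the best so far.  ``patience=None`` disables early
    stopping (used inside the halving search where the rung sets the budget).
    """
    train_idx = np.asarray(fold["inner_train"])
    val_idx = np.asarray(fold["inner_val"])
    if len(train_idx) == 0 or len(val_idx) == 0:
        raise ValueError("empty training or validation split")

    params = init_params(model_config, hyperparams["sigma_motifs"], hyperparams["sigma_net"], rng)
    opt = _Adam(params, lr=hyperparams["lr"])
    batch = int(hyperparams.get("batch_size", 64))
    cols_val = cols[val_idx]
    y_val = targets[val_idx]

    best_mse = np.inf
    best_params = params.copy()
    best_epoch = -1
    history: list[float] = []
    stale = 0
    for epoch in range(epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), batch):
            sel = train_idx[order[start:start + batch]]
            loss, grads = loss_and_grads(params, cols[sel], targets[sel])
            if not np.isfinite(loss):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}; try a lower learning rate "
                    f"(lr={hyperparams['lr']:.3g})")
            opt.step(params, grads)
        val_pred, _ = forward(params, None, cols=cols_val)
        val_mse = mse_loss(val_pred, y_val)
        history.append(val_mse)
        if val_mse < best_mse:
            best_mse = val_mse
            best_params = params.copy()
            best_epoch = epoch
            stale = 0
        else:
            stale += 1
            if patience is not None and stale >= patience:
                break
    logger.debug("fold trained: best val MSE %.5f at epoch %d/%d", best_mse, best_epoch, len(history))
    return Checkpoint(
        params=best_params,
        config=model_config,
        train_ids=train_idx,
        val_ids=val_idx,
        test_ids=np.asarray(fold["outer_test"]),
        best_val_mse=best_mse,
        history=history,
        hyperparams=dict(hyperparams),
    )


# ---------------------------------------------------------------------------
# Successive-halving hyperparameter search
# ---------------------------------------------------------------------------

def hyperparameter_search(cols: np.ndarray, targets: np.ndarray, fold: dict,
                          model_config: ModelConfig, priors: HyperPriors,
                          rng: np.random.Generator, eta: int = 3, n_rungs: int = 3) -> dict:
    """Random configurations winnowed by synchronous successive halving.

    ``num_calibrations`` candidates start at a small epoch budget; the top
    1/eta by inner-validation MSE are promoted to each subsequent rung until
    the full epoch count.  Returns the configuration with the lowest
    validation MSE observed anywhere in the schedule.
    """
    n_candidates = priors.num_calibrations
    candidates = [sample_hyperparams(priors, rng) for _ in range(n_candidates)]
    if n_candidates == 1:
        return candidates[0]
    seeds = rng.integers(0, 2**31 - 1, size=n_candidates)
    rung_epochs = [max(1, int(np.ceil(priors.epochs / eta ** (n_rungs - 1 - r))))
                   for r in range(n_rungs)]

    best_overall = (np.inf, candidates[0])
    alive = list(range(n_candidates))
    for r, budget in enumerate(rung_epochs):
        scores = []
        for ci in alive:
            ckpt = train_model(cols, targets, fold, model_config, candidates[ci],
                               epochs=budget, rng=np.random.default_rng(seeds[ci]),
                               patience=None)
            scores.append(ckpt.best_val_mse)
            if ckpt.best_val_mse < best_overall[0]:
                best_overall = (ckpt.best_val_mse, candidates[ci])
        if r < n_rungs - 1:
            keep = max(1, len(alive) // eta)
            order = np.argsort(scores, kind="stable")[:keep]
            alive = [alive[i] for i in order]
    return dict(best_overall[1])


# ---------------------------------------------------------------------------
# Evaluation with permutation controls
# ---------------------------------------------------------------------------

def explained_variance(pred: np.ndarray, observed: np.ndarray) -> float:
    """Squared Pearson r between prediction and observation, averaged over pools.

    Pools whose predicted or observed vector is constant contribute nothing
    (their correlation is undefined) and are skipped.
    """
    r2 = []
    for j in range(observed.shape[1]):
        x, y = pred[:, j], observed[:, j]
        if np.std(x) == 0 or np.std(y) == 0:
            continue
        r2.append(np.corrcoef(x, y)[0, 1] ** 2)
    return float(np.mean(r2)) if r2 else float("nan")


def evaluate(checkpoint: Checkpoint, sequences: SequenceSet, targets: np.ndarray,
             rng: np.random.Generator, subset: str = "outer_test") -> dict:
    """Held-out explained variance plus two negative controls.

    ``scrambled_sequences``: nucleotides of each held-out sequence are
    permuted (destroying motifs but preserving composition) before
    prediction.  ``permuted_pools``: the pool order of the observed targets
    is permuted before scoring.  Both should undercut the intact score when
    the model has learned sequence- and pool-specific structure.
    """
    idx = {"outer_test": checkpoint.test_ids, "inner_val": checkpoint.val_ids}[subset]
    X = sequences.onehot[idx]
    Y = targets[idx]
    pred, _ = forward(checkpoint.params, X)
    r2 = explained_variance(pred, Y)

    scramble = np.stack([seq[:, rng.permutation(seq.shape[1])] for seq in X])
    pred_scr, _ = forward(checkpoint.params, scramble)
    r2_scr = explained_variance(pred_scr, Y)

    r2_perm = explained_variance(pred, Y[:, rng.permutation(Y.shape[1])])
    return {"r2": r2, "r2_scrambled_sequences": r2_scr, "r2_permuted_pools": r2_perm}


# ---------------------------------------------------------------------------
# Ensemble over folds
# ---------------------------------------------------------------------------

@dataclass
class TrainedEnsemble:
    checkpoints: list[Checkpoint]
    metrics: pd.DataFrame = field(default=None)

    @property
    def K(self) -> int:
        return len(self.checkpoints)


def align_inputs(sequences: SequenceSet, pooled: PooledDataset):
    """Subset sequences and pooled rows to their shared ids, in sequence order."""
    pooled_index = {f: i for i, f in enumerate(pooled.feature_ids)}
    keep = [i for i, s in enumerate(sequences.ids) if s in pooled_index]
    if not keep:
        raise ValueError("no shared ids between sequences and pooled features")
    seqs = sequences.subset(np.array(keep))
    rows = np.array([pooled_index[s] for s in seqs.ids])
    return seqs, pooled.values[rows]


def train_ensemble(sequences: SequenceSet, targets: np.ndarray, model_config: ModelConfig,
                   K: int, epochs: int, rng: np.random.Generator,
                   hyperparams: dict | None = None, priors: HyperPriors | None = None,
                   evaluate_folds: bool = True) -> TrainedEnsemble:
    """Train one model per outer fold (ensemble size r = K).

    Either a fixed ``hyperparams`` dict is reused for every fold, or
    ``priors`` triggers a per-fold successive-halving search.
    """
    if (hyperparams is None) == (priors is None):
        raise ValueError("pass exactly one of hyperparams or priors")
    cols = im2col(sequences.onehot, model_config.m)
    plan = make_cv_plan(len(sequences), K, rng)
    checkpoints = []
    rows = []
    for k, fold in enumerate(plan.folds):
        hp = hyperparams or hyperparameter_search(cols, targets, fold, model_config, priors, rng)
        ckpt = train_model(cols, targets, fold, model_config, hp, epochs=epochs, rng=rng)
        assert len(np.intersect1d(ckpt.train_ids, ckpt.test_ids)) == 0
        checkpoints.append(ckpt)
        row = {"fold": k, "best_val_mse": ckpt.best_val_mse, **hp}
        if evaluate_folds:
            row.update(evaluate(ckpt, sequences, targets, rng))
        rows.append(row)
        logger.info("fold %d/%d done (val MSE %.5f)", k + 1, K, ckpt.best_val_mse)
    return TrainedEnsemble(checkpoints=checkpoints, metrics=pd.DataFrame(rows))
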