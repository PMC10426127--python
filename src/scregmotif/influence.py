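"""Leave-one-out influence scores and their aggregation.

The influence of filter (motif) i on pool j is the mean, over the model's
validation sequences, of the drop in predicted activity when every
parameter belonging to that filter — its convolutional weights and its row
of the readout — is set to zero.  Because a zeroed filter produces
ELU(0) = 0 at every position and the readout is linear, the perturbation
removes exactly that filter's additive contribution; the scores from the d
filters of each of the K ensemble models are stacked into a dK x p matrix.
Scores are then averaged over the pools of each cell type and summed over
the motifs of each reproducible cluster.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from scregmotif.data_io import SequenceSet
from scregmotif.motif_discovery import NON_ALIGNED
from scregmotif.network import Checkpoint, conv_activations

logger = logging.getLogger(__name__)


def loo_influence(checkpoint: Checkpoint, sequences: SequenceSet,
                  subset: np.ndarray | None = None, run: int = 0) -> pd.DataFrame:
    """Motif x pool influence matrix n_ij for one model.

    For each filter i, the intact prediction b_ijk and the prediction c_ijk
    of the model with filter i ablated are compared on the N validation
    sequences: n_ij = mean_k (b_ijk - c_ijk).  Rows are named
    "<run>_<filter>", columns are pool indices.
    """
    if subset is None:
        subset = checkpoint.val_ids
    subset = np.asarray(subset)
    if subset.size == 0:
        raise ValueError("validation set is empty")
    X = sequences.onehot[subset]
    params = checkpoint.params
    act = conv_activations(params, X)                  # (N, d)
    intact = act @ params.fc_weights + params.fc_bias  # b_.jk

    n = np.zeros((params.d, params.p))
    for i in range(params.d):
        ablated = act.copy()
        ablated[:, i] = 0.0  # zeroed conv weights give ELU(0)=0 for this filter
        perturbed = ablated @ params.fc_weights + params.fc_bias  # c_ijk
        n[i] = (intact - perturbed).mean(axis=0)
    return pd.DataFrame(n, index=[f"{run}_{i}" for i in range(params.d)],
                        columns=[f"pool_{j}" for j in range(params.p)])


def ensemble_influence(checkpoints: list[Checkpoint], sequences: SequenceSet) -> pd.DataFrame:
    """Stack per-model influence matrices into dK rows, keeping (run, filter) names."""
    return pd.concat([loo_influence(ckpt, sequences, run=r)
                      for r, ckpt in enumerate(checkpoints)], axis=0)


def aggregate_influence(influence: pd.DataFrame, pool_celltype: list[str],
                        assignment: pd.DataFrame,
                        require_retained: bool = True) -> pd.DataFrame:
    """Collapse motif x pool scores to cluster x cell type.

    Pools of the same cell type are averaged; motifs assigned to the same
    cluster are summed.  Non-aligned motifs, and (by default) motifs in
    clusters that failed the reproducibility filter, are excluded.
    """
    if len(pool_celltype) != influence.shape[1]:
        raise ValueError("pool_celltype length does not match influence columns")
    by_type = mean_by_celltype(influence, pool_celltype)

    labels = assignment.reindex(by_type.index)
    keep = labels["cluster"].notna() & (labels["cluster"] != NON_ALIGNED)
    if require_retained and "retained" in labels:
        keep &= labels["retained"].eq(True)
    kept = by_type[keep.to_numpy()]
    groups = labels.loc[keep.to_numpy(), "cluster"]
    return kept.groupby(groups.to_numpy()).sum().sort_index()


def mean_by_celltype(matrix: pd.DataFrame, pool_celltype: list[str]) -> pd.DataFrame:
    """Average columns (pools) sharing a cell type label."""
    ct = np.asarray(pool_celltype)
    unknown = pd.isna(ct)
    if unknown.any():
        raise ValueError("pool cell type labels contain missing values")
    return matrix.T.groupby(ct).mean().T.sort_index(axis=1)


def z_transform(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-row z-score with population SD; constant rows map to zeros.

    Highlights cell type-specific deviations of each motif's influence
    around its own mean level.
    """
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, keepdims=True)  # population SD (ddof=0)
    constant = sd[:, 0] == 0
    if constant.any():
        logger.warning("%d constant rows z-transformed to zeros", int(constant.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(sd > 0, (values - mean) / np.where(sd == 0, 1, sd), 0.0)
    return pd.DataFrame(z, index=matrix.index, columns=matrix.columns)
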