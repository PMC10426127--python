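"""Relating influence scores to TF expression, gene sets and sequence content.

All correlation work uses Spearman's rank correlation across pools — the
pools, not the cells, are the observational unit throughout — with
Benjamini-Hochberg control when many pairs are tested.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from statsmodels.stats.multitest import multipletests

from scregmotif.data_io import SequenceSet
from scregmotif.network import Checkpoint, conv_activations

logger = logging.getLogger(__name__)


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvalues, float), method="fdr_bh")[1]


def _spearman(x: np.ndarray, y: np.ndarray):
    if np.std(x) == 0 or np.std(y) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# TF <-> motif cluster association
# ---------------------------------------------------------------------------

def tf_correlation(cluster_influence: pd.DataFrame, tf_expression: pd.DataFrame,
                   tf_clusters: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Rank candidate TFs for each motif cluster by influence correlation.

    For every (cluster, TF) pair where the TF's binding preference belongs to
    the cluster, the Spearman correlation between the cluster's summed
    influence scores and the TF's expression across pools is computed;
    p-values are BH-adjusted over all tested pairs.  TFs whose expression is
    constant across pools get a missing rho with a warning.

    ``cluster_influence``: clusters x pools.  ``tf_expression``: TFs x pools
    (same pool order).  ``tf_clusters``: columns id (TF) and cluster.
    """
    if list(cluster_influence.columns) != list(tf_expression.columns):
        raise ValueError("pool columns of influence and expression matrices differ")
    rows = []
    for tf, cluster in zip(tf_clusters["id"], tf_clusters["cluster"]):
        if cluster not in cluster_influence.index or tf not in tf_expression.index:
            continue
        x = cluster_influence.loc[cluster].to_numpy(float)
        y = tf_expression.loc[tf].to_numpy(float)
        rho, p = _spearman(x, y)
        if np.isnan(rho):
            logger.warning("constant vector for (%s, %s); correlation undefined", cluster, tf)
        rows.append({"cluster": cluster, "tf": tf, "rho": rho, "p": p,
                     "mean_expression": float(np.mean(y))})
    table = pd.DataFrame(rows)
    if len(table):
        tested = table["p"].notna()
        table["q"] = np.nan
        if tested.any():
            table.loc[tested, "q"] = bh_adjust(table.loc[tested, "p"].to_numpy())
        table["significant"] = table["q"] < alpha
    return table


# ---------------------------------------------------------------------------
# Gene-set (e.g. GO) correlation
# ---------------------------------------------------------------------------

def gene_set_correlation(pooled_expression: pd.DataFrame, gene_sets: dict[str, list[str]],
                         cluster_influence: pd.DataFrame, max_set_size: int = 50,
                         top_n: int = 500, n_groups: int = 3):
    """Correlate small gene programs with motif-cluster influence across pools.

    Sets with ``max_set_size`` or more genes are discarded; each surviving
    set is summarized as the mean pooled expression of its member genes, and
    Spearman-correlated with every cluster's influence row.  The ``top_n``
    sets by maximum correlation are hierarchically clustered
    (average linkage, Euclidean distance) and the tree is cut into
    ``n_groups`` groups.

    Returns ``(correlations, groups)``: a set x cluster frame (top sets only)
    and a Series of group labels.
    """
    if list(pooled_expression.columns) != list(cluster_influence.columns):
        raise ValueError("pool columns of expression and influence matrices differ")
    rows = {}
    for name, genes in gene_sets.items():
        if len(genes) >= max_set_size:
            continue
        present = [g for g in genes if g in pooled_expression.index]
        if not present:
            logger.warning("gene set %s has no matching genes; skipped", name)
            continue
        profile = pooled_expression.loc[present].mean(axis=0).to_numpy(float)
        rows[name] = [
            _spearman(profile, cluster_influence.loc[c].to_numpy(float))[0]
            for c in cluster_influence.index
        ]
    corr = pd.DataFrame.from_dict(rows, orient="index", columns=list(cluster_influence.index))
    if corr.empty:
        return corr, pd.Series(dtype=int)
    top = corr.loc[corr.max(axis=1).sort_values(ascending=False).index[:top_n]]
    if len(top) > 1:
        link = hierarchy.linkage(top.to_numpy(), method="average", metric="euclidean")
        labels = hierarchy.fcluster(link, t=min(n_groups, len(top)), criterion="maxclust")
    else:
        labels = np.ones(len(top), dtype=int)
    return top, pd.Series(labels, index=top.index, name="group")


# ---------------------------------------------------------------------------
# Sequence "motif space"
# ---------------------------------------------------------------------------

def motif_space(checkpoints: list[Checkpoint], sequences: SequenceSet) -> pd.DataFrame:
    """Per-sequence post-ELU max-pooled activations across the whole ensemble.

    Columns are ordered run-major, filter-minor ("<run>_<filter>"), giving an
    n_sequences x (r*d) matrix — the coordinates in which similarly regulated
    sequences cluster together.
    """
    blocks = []
    names = []
    for run, ckpt in enumerate(checkpoints):
        blocks.append(conv_activations(ckpt.params, sequences.onehot))
        names.extend(f"{run}_{i}" for i in range(ckpt.params.d))
    return pd.DataFrame(np.concatenate(blocks, axis=1), index=sequences.ids, columns=names)


def family_activation(space: pd.DataFrame, assignment: pd.DataFrame,
                      require_retained: bool = True) -> pd.DataFrame:
    """Sum motif-space columns over the motifs of each cluster (family)."""
    from scregmotif.motif_discovery import NON_ALIGNED

    labels = assignment.reindex(space.columns)
    keep = labels["cluster"].notna() & (labels["cluster"] != NON_ALIGNED)
    if require_retained and "retained" in labels:
        keep &= labels["retained"].eq(True)
    kept = space.loc[:, keep.to_numpy()]
    groups = labels.loc[keep.to_numpy(), "cluster"]
    return kept.T.groupby(groups.to_numpy()).sum().T.sort_index(axis=1)


def co_occurrence_sets(family_scores: pd.DataFrame, frac_of_max: float = 0.75):
    """Genes carrying each motif family, and how the carrier sets overlap.

    A gene belongs to a family's set when its summed activation exceeds
    ``frac_of_max`` of the family's maximum gene score.  Families whose
    maximum score is not positive get an empty set with a warning.  Returns
    ``(sets, intersections)`` where intersections is a family x family count
    matrix (diagonal = set sizes).
    """
    sets: dict[str, set] = {}
    for fam in family_scores.columns:
        scores = family_scores[fam]
        top = scores.max()
        if top <= 0:
            logger.warning("family %s has no positive scores; empty set", fam)
            sets[fam] = set()
        else:
            sets[fam] = set(scores.index[scores > frac_of_max * top])
    fams = list(family_scores.columns)
    inter = pd.DataFrame(0, index=fams, columns=fams, dtype=int)
    for a in fams:
        for b in fams:
            inter.loc[a, b] = len(sets[a] & sets[b])
    return sets, inter


# ---------------------------------------------------------------------------
# Signature scoring
# ---------------------------------------------------------------------------

def signature_score(pooled_expression: pd.DataFrame, genes: list[str]) -> pd.Series:
    """Mean pooled expression of the signature genes present, per pool."""
    present = [g for g in genes if g in pooled_expression.index]
    if not present:
        raise ValueError("none of the signature genes are present")
    if len(present) < len(genes):
        logger.info("signature: %d/%d genes present", len(present), len(genes))
    return pooled_expression.loc[present].mean(axis=0)


def correlate_with_covariate(influence_row: pd.Series, covariate: pd.Series):
    """Spearman rho and p between an influence row and a per-pool covariate."""
    joined = pd.concat([influence_row, covariate], axis=1, join="inner").dropna()
    return _spearman(joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float))
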