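"""Cell pooling: geometric-coverage seed sampling and kNN count aggregation.

Single-cell count matrices are dominated by zeros.  Summing the raw counts of
each seed cell and its nearest neighbours in a low-dimensional embedding
yields a denser "pooled" matrix whose columns still track cell states.  Seeds
are chosen by covering-grid sampling so that rare populations, which occupy
little probability mass but real volume in the embedding, are still
represented.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.neighbors import NearestNeighbors

from scregmotif.data_io import CountMatrix

logger = logging.getLogger(__name__)

# Dataset presets: (min_detect_frac, rescue_frac, rescue_mean_threshold).
# The rescue threshold is compared against the mean of a feature's non-zero
# log1p pooled values, using the literal constants log10(3) / log10(4).
FILTER_PRESETS = {
    "kidney": (0.05, 0.16, float(np.log10(3))),
    "tabula-muris": (0.03, 0.08, float(np.log10(4))),
    "brain": (0.06, 0.15, float(np.log10(4))),
}


@dataclass
class PoolingConfig:
    n_pools: int = 1000
    pool_size: int = 100
    include_seed: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pools < 1 or self.pool_size < 1:
            raise ValueError("n_pools and pool_size must be >= 1")


@dataclass
class PooledDataset:
    """log1p-transformed pooled counts (features x pools) with pool annotation."""

    values: np.ndarray
    feature_ids: list[str]
    pool_ids: list[str]
    pool_members: list[list[str]]
    pool_celltype: list[str]
    pool_purity: np.ndarray
    raw_sums: np.ndarray = field(default=None, repr=False)  # pre-log pooled counts
    pool_n_celltypes: np.ndarray = field(default=None)

    @property
    def n_pools(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.feature_ids, columns=self.pool_ids)

    def sparsity(self) -> float:
        return float(np.mean(self.values == 0))


def geometric_sketch(embedding: np.ndarray, n_seeds: int, rng: np.random.Generator) -> np.ndarray:
    """Pick ``n_seeds`` cells spread evenly over the embedding's occupied volume.

    Binary-searches an axis-aligned hypercube side length until the number of
    occupied cubes is at least ``n_seeds``, then samples one random cell per
    occupied cube, truncating (or topping up with random unsampled cells) to
    exactly ``n_seeds``.  Sampling is per-cube rather than per-cell, so small
    but spatially distinct populations receive far more seeds than their cell
    count alone would give them.
    """
    embedding = np.asarray(embedding, dtype=float)
    n_cells = embedding.shape[0]
    if n_seeds > n_cells:
        raise ValueError(f"n_seeds={n_seeds} exceeds n_cells={n_cells}")
    if n_seeds == n_cells:
        return np.arange(n_cells)

    lo_corner = embedding.min(axis=0)
    span = float(np.max(embedding.max(axis=0) - lo_corner))
    if span == 0:  # all cells coincide
        return rng.choice(n_cells, size=n_seeds, replace=False)

    def occupied(side: float) -> dict[tuple, np.ndarray]:
        keys = np.floor((embedding - lo_corner) / side).astype(np.int64)
        cubes: dict[tuple, list[int]] = {}
        for i, key in enumerate(map(tuple, keys)):
            cubes.setdefault(key, []).append(i)
        return {k: np.array(v) for k, v in cubes.items()}

    # Binary search the largest side whose occupied-cube count is >= n_seeds.
    lo, hi = 0.0, 2.0 * span
    cubes = occupied(span / max(n_seeds, 2))
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mid <= 0:
            break
        candidate = occupied(mid)
        if len(candidate) >= n_seeds:
            cubes = candidate
            lo = mid
        else:
            hi = mid
    keys = sorted(cubes)  # deterministic order before random choices
    picks = np.array([rng.choice(cubes[k]) for k in keys])
    if len(picks) > n_seeds:
        picks = rng.choice(picks, size=n_seeds, replace=False)
    elif len(picks) < n_seeds:
        remaining = np.setdiff1d(np.arange(n_cells), picks)
        extra = rng.choice(remaining, size=n_seeds - len(picks), replace=False)
        picks = np.concatenate([picks, extra])
    return np.sort(picks)


def pool_cells(counts: CountMatrix, seeds: np.ndarray, config: PoolingConfig) -> PooledDataset:
    """Sum raw counts over each seed's kNN neighbourhood, then log1p.

    Each pool holds exactly ``pool_size`` cells: the seed plus its
    ``pool_size - 1`` nearest cells by Euclidean distance in the embedding
    (or, with ``include_seed=False``, the ``pool_size`` nearest non-seed
    cells).  The pool's cell type is the modal member type; ties break
    lexicographically and are logged.
    """
    seeds = np.asarray(seeds)
    if len(np.unique(seeds)) != len(seeds):
        raise ValueError("duplicate seed cells")
    q = config.pool_size
    if q > counts.n_cells:
        raise ValueError(f"pool_size={q} exceeds n_cells={counts.n_cells}")

    n_neighbors = q if config.include_seed else q + 1
    nn = NearestNeighbors(n_neighbors=n_neighbors).fit(counts.embedding)
    _, idx = nn.kneighbors(counts.embedding[seeds])

    members_per_pool: list[np.ndarray] = []
    for row, seed in zip(idx, seeds):
        if config.include_seed:
            # seed is its own nearest neighbour at distance 0
            members = np.concatenate(([seed], row[row != seed]))[:q]
        else:
            members = row[row != seed][:q]
        members_per_pool.append(members)

    mat = counts.values.tocsc()
    raw = np.zeros((mat.shape[0], len(seeds)))
    indicator = sparse.lil_matrix((counts.n_cells, len(seeds)))
    for j, members in enumerate(members_per_pool):
        indicator[members, j] = 1.0
    raw = np.asarray((mat @ indicator.tocsc()).todense())

    types = counts.cell_types().to_numpy()
    pool_ct: list[str] = []
    purity = np.zeros(len(seeds))
    n_types = np.zeros(len(seeds), dtype=int)
    for j, members in enumerate(members_per_pool):
        tally = Counter(types[members])
        top = max(tally.values())
        winners = sorted(t for t, c in tally.items() if c == top)
        if len(winners) > 1:
            logger.info("pool %d: cell type tie %s, keeping %s", j, winners, winners[0])
        pool_ct.append(winners[0])
        purity[j] = top / len(members)
        n_types[j] = len(tally)

    cell_ids = np.asarray(counts.cell_ids)
    return PooledDataset(
        values=np.log1p(raw),
        feature_ids=list(counts.feature_ids),
        pool_ids=[f"pool_{j}" for j in range(len(seeds))],
        pool_members=[cell_ids[m].tolist() for m in members_per_pool],
        pool_celltype=pool_ct,
        pool_purity=purity,
        raw_sums=raw,
        pool_n_celltypes=n_types,
    )


def filter_features(pooled: PooledDataset, min_detect_frac: float, rescue_frac: float,
                    rescue_mean_threshold: float) -> PooledDataset:
    """Drop rarely detected features, rescuing strong but sparse ones.

    Features detected (value > 0) in fewer than ``min_detect_frac`` of pools
    are dropped.  Features detected in fewer than ``rescue_frac`` of pools
    are kept only if the mean of their non-zero values exceeds
    ``rescue_mean_threshold``.  Row order is preserved.
    """
    if not 0 <= min_detect_frac <= rescue_frac <= 1:
        raise ValueError("need 0 <= min_detect_frac <= rescue_frac <= 1")
    detected = pooled.values > 0
    frac = detected.mean(axis=1)
    with np.errstate(invalid="ignore"):
        nz_mean = np.where(detected.any(axis=1),
                           pooled.values.sum(axis=1) / np.maximum(detected.sum(axis=1), 1), 0.0)
    keep = frac >= min_detect_frac
    sparse_rows = frac < rescue_frac
    keep &= ~sparse_rows | (nz_mean > rescue_mean_threshold)
    if not keep.any():
        raise ValueError("no features pass filtering; relax min_detect_frac / rescue thresholds")
    rows = np.flatnonzero(keep)
    return PooledDataset(
        values=pooled.values[rows],
        feature_ids=[pooled.feature_ids[i] for i in rows],
        pool_ids=pooled.pool_ids,
        pool_members=pooled.pool_members,
        pool_celltype=pooled.pool_celltype,
        pool_purity=pooled.pool_purity,
        raw_sums=None if pooled.raw_sums is None else pooled.raw_sums[rows],
        pool_n_celltypes=pooled.pool_n_celltypes,
    )


def pooling_report(pooled: PooledDataset) -> dict:
    """Summary statistics: per-pool purity and type counts, cell reuse, sparsity."""
    inclusion = Counter(c for members in pooled.pool_members for c in members)
    per_pool = pd.DataFrame({
        "pool_id": pooled.pool_ids,
        "cell_type": pooled.pool_celltype,
        "purity": pooled.pool_purity,
        "n_cell_types": pooled.pool_n_celltypes,
    })
    return {
        "per_pool": per_pool,
        "cell_inclusion_counts": pd.Series(inclusion, name="times_pooled"),
        "sparsity": pooled.sparsity(),
    }
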