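"""Ground-truth synthetic data: planted motifs and cell-type-specific effects.

The generator emulates the pipeline's two inputs.  Sequences are i.i.d.
background nucleotides with motif instances planted at non-overlapping
positions, each instance drawn column-wise from the motif's PPM.  Activity
is additive on the pooled log scale: a sequence's expected value in a pool
of cell type t is ``baseline + sum_i count_i * W[i, t]`` where count_i is
the number of planted instances of motif i (0/1 under Bernoulli planting).
Cells live in well-separated Gaussian blobs (one per cell type) in a 2-D
embedding, and raw per-cell counts are Poisson draws whose rates are chosen
so that summing a pool of q same-type cells and applying log1p recovers the
expected value in expectation.

Every quantity needed to score a pipeline stage — instance positions,
per-sequence motif counts, the effect matrix W, expected pool values — is
recorded in :class:`GroundTruth`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

from scregmotif.data_io import ALPHABET, CountMatrix, SequenceSet
from scregmotif.pooling import PooledDataset

logger = logging.getLogger(__name__)

# Sharp default motifs: distinct 12-nt consensi, dominant base probability 0.88.
DEFAULT_CONSENSI = (
    "TGACTCAGCAGT",
    "CACGTGTTGACC",
    "GGGCGGTAGTGA",
    "TTTACGCCAATT",
    "CAGGAACCTGAG",
)
_DOMINANT_P = 0.88


def consensus_ppm(consensus: str, dominant: float = _DOMINANT_P) -> np.ndarray:
    ppm = np.full((4, len(consensus)), (1 - dominant) / 3)
    for j, base in enumerate(consensus):
        ppm[ALPHABET.index(base), j] = dominant
    return ppm


def _default_effects(n_motifs: int, n_celltypes: int) -> np.ndarray:
    """One dominant cell type per motif, cycling; magnitude 2 on the log scale."""
    W = np.zeros((n_motifs, n_celltypes))
    for i in range(n_motifs):
        W[i, i % n_celltypes] = 2.0
        W[i, (i + 1) % n_celltypes] = 0.5
    return W


@dataclass
class SimulationConfig:
    n_sequences: int = 2000
    L: int = 200
    motif_ppms: list = None          # defaults to the five consensus motifs
    planting_prob: float = 0.3       # per (sequence, motif) Bernoulli
    gc: float = 0.5                  # background GC fraction
    n_cells: int = 500
    n_celltypes: int = 4
    n_pools: int = 50
    pool_size: int = 10              # cells per pool (q)
    effects: np.ndarray = None       # (n_motifs, n_celltypes), defaults above
    baseline: float = 1.0            # pooled log1p value with no motifs
    noise_sd: float = 0.1            # Gaussian noise on pooled values
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.motif_ppms is None:
            self.motif_ppms = [consensus_ppm(c) for c in DEFAULT_CONSENSI]
        self.motif_ppms = [np.asarray(p, dtype=float) for p in self.motif_ppms]
        if self.effects is None:
            self.effects = _default_effects(len(self.motif_ppms), self.n_celltypes)
        self.effects = np.asarray(self.effects, dtype=float)
        if self.effects.shape != (len(self.motif_ppms), self.n_celltypes):
            raise ValueError("effects must be (n_motifs, n_celltypes)")
        if not 0 <= self.planting_prob <= 1:
            raise ValueError("planting_prob must be in [0, 1]")
        for ppm in self.motif_ppms:
            if ppm.shape[1] > self.L:
                raise ValueError("motif wider than sequence length")

    @property
    def n_motifs(self) -> int:
        return len(self.motif_ppms)

    def celltype_names(self) -> list[str]:
        return [f"type_{t}" for t in range(self.n_celltypes)]


@dataclass
class GroundTruth:
    instances: pd.DataFrame            # seq_id, motif, position, instance
    counts: np.ndarray                 # (n_sequences, n_motifs) planted copies
    effects: np.ndarray                # W, (n_motifs, n_celltypes)
    expected: np.ndarray = None        # (n_sequences, n_celltypes) pooled values
    celltypes: list = None


def simulate_sequences(config: SimulationConfig, rng: np.random.Generator):
    """Background sequences with independently planted, non-overlapping motifs.

    Returns ``(SequenceSet, GroundTruth)``; the truth records every planted
    instance with its position and sampled letters.  If a motif cannot be
    placed without overlap after 100 tries it is skipped with a warning.
    """
    base_p = np.array([(1 - config.gc) / 2, config.gc / 2, config.gc / 2, (1 - config.gc) / 2])
    letters = np.array(list(ALPHABET))
    records: list[dict] = []
    sequences: list[str] = []
    counts = np.zeros((config.n_sequences, config.n_motifs), dtype=int)
    for k in range(config.n_sequences):
        seq = list(rng.choice(letters, size=config.L, p=base_p))
        occupied: list[tuple[int, int]] = []
        for i, ppm in enumerate(config.motif_ppms):
            if rng.random() >= config.planting_prob:
                continue
            w = ppm.shape[1]
            start = None
            for _ in range(100):
                cand = int(rng.integers(0, config.L - w + 1))
                if all(cand + w <= lo or cand >= hi for lo, hi in occupied):
                    start = cand
                    break
            if start is None:
                logger.warning("seq %d: could not place motif %d without overlap; skipped", k, i)
                continue
            instance = "".join(ALPHABET[rng.choice(4, p=ppm[:, j] / ppm[:, j].sum())]
                               for j in range(w))
            seq[start:start + w] = list(instance)
            occupied.append((start, start + w))
            counts[k, i] += 1
            records.append({"seq_id": f"seq_{k}", "motif": i, "position": start,
                            "instance": instance})
        sequences.append("".join(seq))
    seqset = SequenceSet.from_sequences([f"seq_{k}" for k in range(config.n_sequences)], sequences)
    truth = GroundTruth(
        instances=pd.DataFrame(records, columns=["seq_id", "motif", "position", "instance"]),
        counts=counts,
        effects=config.effects,
        celltypes=config.celltype_names(),
    )
    return seqset, truth


def simulate_cells(config: SimulationConfig, rng: np.random.Generator):
    """Cell type labels and a blob-per-type 2-D embedding.

    Types are assigned round-robin (balanced); blobs sit on a circle of
    radius 10 with within-blob SD 0.5, i.e. well separated relative to their
    spread so that kNN pools are nearly pure.
    """
    types = np.array([t % config.n_celltypes for t in range(config.n_cells)])
    angles = 2 * np.pi * np.arange(config.n_celltypes) / config.n_celltypes
    centers = 10.0 * np.column_stack([np.cos(angles), np.sin(angles)])
    embedding = centers[types] + rng.normal(0.0, 0.5, size=(config.n_cells, 2))
    names = config.celltype_names()
    labels = [names[t] for t in types]
    return labels, embedding


def simulate_pooled_targets(truth: GroundTruth, config: SimulationConfig,
                            rng: np.random.Generator):
    """Pooled targets with known effects, plus matching raw counts.

    Returns ``(pooled, count_matrix)``.  The pooled values are the expected
    log1p values per (sequence, pool cell type) plus Gaussian noise, floored
    at zero; pools are annotated with their (pure) cell type.  The raw
    ``CountMatrix`` draws each cell's counts from Poisson rates
    ``expm1(expected) / pool_size`` so the pooling module applied to a pure
    pool of ``pool_size`` cells reproduces the targets in expectation.
    """
    n_seq = truth.counts.shape[0]
    expected = config.baseline + truth.counts @ config.effects  # (n_seq, n_celltypes)
    truth.expected = expected

    cell_labels, embedding = simulate_cells(config, rng)
    names = config.celltype_names()
    type_index = {name: t for t, name in enumerate(names)}
    cells_by_type = {name: [i for i, lab in enumerate(cell_labels) if lab == name]
                     for name in names}

    pool_types = [names[j % config.n_celltypes] for j in range(config.n_pools)]
    members = []
    for j, name in enumerate(pool_types):
        candidates = cells_by_type[name]
        take = rng.choice(candidates, size=min(config.pool_size, len(candidates)), replace=False)
        members.append([f"cell_{c}" for c in take])

    noise = rng.normal(0.0, config.noise_sd, size=(n_seq, config.n_pools))
    values = np.maximum(expected[:, [type_index[t] for t in pool_types]] + noise, 0.0)
    pooled = PooledDataset(
        values=values,
        feature_ids=[f"seq_{k}" for k in range(n_seq)],
        pool_ids=[f"pool_{j}" for j in range(config.n_pools)],
        pool_members=members,
        pool_celltype=pool_types,
        pool_purity=np.ones(config.n_pools),
        pool_n_celltypes=np.ones(config.n_pools, dtype=int),
    )

    rates = np.expm1(expected) / config.pool_size           # (n_seq, n_celltypes)
    type_of_cell = np.array([type_index[lab] for lab in cell_labels])
    raw = rng.poisson(rates[:, type_of_cell])               # (n_seq, n_cells)
    meta = pd.DataFrame({
        "cell_id": [f"cell_{c}" for c in range(config.n_cells)],
        "cell_type": cell_labels,
        "batch": "batch_0",
    }).set_index("cell_id")
    count_matrix = CountMatrix(
        values=sparse.csr_matrix(raw),
        feature_ids=[f"seq_{k}" for k in range(n_seq)],
        cell_ids=[f"cell_{c}" for c in range(config.n_cells)],
        cell_meta=meta,
        embedding=embedding,
    )
    return pooled, count_matrix


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    sequences: SequenceSet
    truth: GroundTruth
    pooled: PooledDataset
    counts: CountMatrix


def simulate_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """One-call generator: sequences, truth, pooled targets and raw counts."""
    config = config or SimulationConfig()
    rng = np.random.default_rng(config.rng_seed)
    sequences, truth = simulate_sequences(config, rng)
    pooled, counts = simulate_pooled_targets(truth, config, rng)
    return SimulatedDataset(config=config, sequences=sequences, truth=truth,
                            pooled=pooled, counts=counts)
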