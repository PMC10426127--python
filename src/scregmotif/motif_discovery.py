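"""From convolutional filters to motifs: PFM extraction, alignment, clustering.

A trained filter is summarized by the subsequences it responds to: for every
training sequence, the window of width m with the highest positive post-ELU
activation contributes its nucleotides to the filter's position frequency
matrix (PFM); sequences with no positive activation for a filter are left
out.  Filters are then matched to a motif database — through the MEME
suite's Tomtom when the executable is available, otherwise through a
built-in comparator that scores the best mean per-column Pearson correlation
over all ungapped offsets and both orientations, with an empirical p-value
from column-shuffled motifs — and assigned to pre-specified motif clusters
via their most significant alignment.  A cluster counts as reproducible only
if filters from at least half of the ensemble's models land in it.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from scregmotif.data_io import SequenceSet, write_meme
from scregmotif.network import Checkpoint, conv_activations

logger = logging.getLogger(__name__)

MEME_EXPORT_PSEUDOCOUNT = 1e-4  # avoids zero probabilities in written files


@dataclass
class Motif:
    name: str         # "<run>_<filter>"
    run: int
    filter_index: int
    pfm: np.ndarray   # 4 x m integer counts
    ppm: np.ndarray   # 4 x m column-normalized
    n_contributing: int


@dataclass
class MotifSet:
    motifs: list[Motif]

    def __len__(self) -> int:
        return len(self.motifs)

    def valid(self) -> list[Motif]:
        return [m for m in self.motifs if m.n_contributing > 0]

    def to_ppm_dict(self) -> dict[str, np.ndarray]:
        return {m.name: m.ppm for m in self.valid()}

    def write_meme(self, path) -> None:
        write_meme(self.to_ppm_dict(), path, pseudocount=MEME_EXPORT_PSEUDOCOUNT)

    def runs(self) -> dict[str, int]:
        return {m.name: m.run for m in self.motifs}


# ---------------------------------------------------------------------------
# PFM extraction
# ---------------------------------------------------------------------------

def extract_pfms(checkpoint: Checkpoint, sequences: SequenceSet, run: int = 0,
                 subset: np.ndarray | None = None) -> MotifSet:
    """Build one PFM per filter from max-activating training subsequences.

    ``subset`` restricts extraction to given sequence indices (by default the
    checkpoint's inner-training split when available, else all sequences).
    Ties in the max-activation position resolve to the lowest position.
    Filters with no positively activated sequence get an empty PFM and are
    excluded by :meth:`MotifSet.valid`.
    """
    if subset is None:
        subset = checkpoint.train_ids if len(checkpoint.train_ids) else np.arange(len(sequences))
    seqs = sequences.subset(np.asarray(subset))
    m = checkpoint.params.m
    act, argmax = conv_activations(checkpoint.params, seqs.onehot, return_argmax=True)
    motifs: list[Motif] = []
    offsets = np.arange(m)
    for i in range(checkpoint.params.d):
        contributing = np.flatnonzero(act[:, i] > 0)
        pfm = np.zeros((4, m), dtype=np.int64)
        if contributing.size:
            starts = argmax[contributing, i]
            windows = seqs.indices[contributing[:, None], starts[:, None] + offsets]  # (c, m)
            for col in range(m):
                bases = windows[:, col]
                counts = np.bincount(bases[bases >= 0], minlength=4)
                pfm[:, col] = counts
        n_contrib = int(contributing.size)
        with np.errstate(invalid="ignore", divide="ignore"):
            colsums = pfm.sum(axis=0)
            ppm = np.where(colsums > 0, pfm / np.maximum(colsums, 1), 0.0)
        if n_contrib == 0:
            logger.warning("filter %d_%d has no positively activated sequences", run, i)
        motifs.append(Motif(name=f"{run}_{i}", run=run, filter_index=i,
                            pfm=pfm, ppm=ppm, n_contributing=n_contrib))
    return MotifSet(motifs=motifs)


def extract_ensemble_pfms(checkpoints: list[Checkpoint], sequences: SequenceSet) -> MotifSet:
    """Concatenate per-model MotifSets; motif names keep (run, filter) identity."""
    motifs: list[Motif] = []
    for run, ckpt in enumerate(checkpoints):
        motifs.extend(extract_pfms(ckpt, sequences, run=run).motifs)
    return MotifSet(motifs=motifs)


# ---------------------------------------------------------------------------
# PPM comparison (built-in comparator)
# ---------------------------------------------------------------------------

def reverse_complement_ppm(ppm: np.ndarray) -> np.ndarray:
    return ppm[::-1, ::-1]


def _standardize_columns(ppm: np.ndarray) -> np.ndarray:
    """Center each 4-vector column and scale to unit norm (constant -> zeros)."""
    centered = ppm - ppm.mean(axis=0, keepdims=True)
    norms = np.linalg.norm(centered, axis=0, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(norms > 1e-12, centered / np.where(norms == 0, 1, norms), 0.0)


def _offset_scores(C: np.ndarray, min_overlap: int) -> np.ndarray:
    """Mean of per-column correlations along each ungapped offset diagonal.

    ``C[i, j]`` is the correlation of query column i with target column j;
    offsets shift the target start relative to the query.
    """
    m, w = C.shape
    scores = []
    for offset in range(-(m - min_overlap), w - min_overlap + 1):
        qi = np.arange(max(0, -offset), min(m, w - offset))
        if len(qi) < min_overlap:
            continue
        scores.append(C[qi, qi + offset].mean())
    return np.asarray(scores)


def ppm_similarity(query: np.ndarray, target: np.ndarray, min_overlap: int = 4):
    """Best mean per-column Pearson r over ungapped offsets and orientations.

    Returns ``(score, offset, orientation)`` where offset is the target
    start relative to the query start and orientation is '+' or '-'.
    """
    qs = _standardize_columns(np.asarray(query, float))
    best = (-np.inf, 0, "+")
    for orient, t in (("+", np.asarray(target, float)),
                      ("-", reverse_complement_ppm(np.asarray(target, float)))):
        C = qs.T @ _standardize_columns(t)
        m, w = C.shape
        offsets = list(range(-(m - min_overlap), w - min_overlap + 1))
        scores = _offset_scores(C, min_overlap)
        for off, sc in zip([o for o in offsets
                            if len(range(max(0, -o), min(m, w - o))) >= min_overlap], scores):
            if sc > best[0]:
                best = (float(sc), off, orient)
    return best


def _best_scores_shuffled(query: np.ndarray, targets: dict[str, np.ndarray],
                          n_shuffles: int, min_overlaps: dict[str, int],
                          rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Null distribution of best alignment scores under query column shuffling.

    A column permutation of the query permutes rows of the precomputed
    correlation matrix, so the null needs no re-correlation.
    """
    qs = _standardize_columns(np.asarray(query, float))
    m = qs.shape[1]
    perms = np.stack([rng.permutation(m) for _ in range(n_shuffles)])
    out: dict[str, np.ndarray] = {}
    for name, target in targets.items():
        min_overlap = min_overlaps[name]
        best = np.full(n_shuffles, -np.inf)
        for t in (np.asarray(target, float), reverse_complement_ppm(np.asarray(target, float))):
            C = qs.T @ _standardize_columns(t)
            Cp = C[perms, :]  # (S, m, w)
            w = C.shape[1]
            for offset in range(-(m - min_overlap), w - min_overlap + 1):
                qi = np.arange(max(0, -offset), min(m, w - offset))
                if len(qi) < min_overlap:
                    continue
                best = np.maximum(best, Cp[:, qi, qi + offset].mean(axis=1))
        out[name] = best
    return out


def _pair_min_overlap(m: int, w: int) -> int:
    # short chance overlaps of one-hot-ish columns score deceptively well;
    # requiring ~2/3 of the shorter motif keeps the shuffle null honest
    return max(4, int(np.ceil(2 * min(m, w) / 3)))


def align_motifs(queries: dict[str, np.ndarray] | MotifSet, database: dict[str, np.ndarray],
                 threshold: float = 0.05, n_shuffles: int = 1000,
                 min_overlap: int | None = None,
                 rng: np.random.Generator | None = None,
                 tomtom_path: str | None = None) -> pd.DataFrame:
    """Align query PPMs against a database; returns one row per (query, target).

    Uses the external Tomtom tool when an executable is found (preferred),
    otherwise the built-in comparator with a column-shuffle empirical
    p-value.  ``min_overlap=None`` requires two thirds of the shorter motif
    to overlap.  Columns: query, target, score, offset, orientation, p, E, q,
    significant (q < threshold).  Which path ran is logged.
    """
    if isinstance(queries, MotifSet):
        queries = queries.to_ppm_dict()
    if not database:
        raise ValueError("empty motif database")
    exe = tomtom_path or shutil.which("tomtom")
    if exe and shutil.which(exe):
        logger.info("aligning %d motifs with Tomtom at %s", len(queries), exe)
        return _align_with_tomtom(queries, database, exe, threshold)
    logger.info("Tomtom not found; using built-in PPM comparator for %d motifs", len(queries))
    rng = rng or np.random.default_rng(0)
    from statsmodels.stats.multitest import multipletests

    rows = []
    for qname, qppm in queries.items():
        overlaps = {tname: (min_overlap if min_overlap is not None
                            else _pair_min_overlap(np.asarray(qppm).shape[1],
                                                   np.asarray(tppm).shape[1]))
                    for tname, tppm in database.items()}
        null = _best_scores_shuffled(qppm, database, n_shuffles, overlaps, rng)
        for tname, tppm in database.items():
            score, offset, orient = ppm_similarity(qppm, tppm, overlaps[tname])
            p = float((1 + np.sum(null[tname] >= score)) / (1 + n_shuffles))
            rows.append({"query": qname, "target": tname, "score": score,
                         "offset": offset, "orientation": orient, "p": p,
                         "E": p * len(database)})
    table = pd.DataFrame(rows)
    if len(table):
        table["q"] = multipletests(table["p"], method="fdr_bh")[1]
        table["significant"] = table["q"] < threshold
    return table


def _align_with_tomtom(queries: dict, database: dict, exe: str, threshold: float) -> pd.DataFrame:
    with tempfile.TemporaryDirectory() as tmp:
        qpath = Path(tmp) / "query.meme"
        dpath = Path(tmp) / "db.meme"
        write_meme(queries, qpath, pseudocount=MEME_EXPORT_PSEUDOCOUNT)
        write_meme(database, dpath, pseudocount=MEME_EXPORT_PSEUDOCOUNT)
        outdir = Path(tmp) / "out"
        subprocess.run([exe, "-thresh", str(threshold), "-oc", str(outdir),
                        str(qpath), str(dpath)], check=True, capture_output=True)
        raw = pd.read_csv(outdir / "tomtom.tsv", sep="\t", comment="#")
    table = raw.rename(columns={
        "Query_ID": "query", "Target_ID": "target", "Optimal_offset": "offset",
        "p-value": "p", "E-value": "E", "q-value": "q", "Orientation": "orientation",
    })[["query", "target", "offset", "orientation", "p", "E", "q"]]
    table["score"] = np.nan
    table["significant"] = table["q"] < threshold
    return table


# ---------------------------------------------------------------------------
# Cluster assignment and reproducibility filter
# ---------------------------------------------------------------------------

NON_ALIGNED = "non-aligned"


def assign_clusters(alignments: pd.DataFrame, cluster_table: pd.DataFrame, n_models: int,
                    motif_runs: dict[str, int] | None = None) -> pd.DataFrame:
    """Label each motif with the cluster of its most significant alignment.

    Most significant = lowest q, ties by lowest p then lexicographic target
    id.  Alignments whose target is missing from the cluster table are
    skipped with a warning.  A cluster is retained only when it contains
    motifs from at least ceil(n_models / 2) distinct models; motifs without
    a significant alignment are labelled "non-aligned" and never retained.

    Returns a frame indexed by motif name with columns cluster, target,
    p, q, run, retained.
    """
    cluster_of = dict(zip(cluster_table["id"], cluster_table["cluster"]))
    sig = alignments[alignments.get("significant", False)].copy() if len(alignments) else alignments
    known = sig["target"].isin(cluster_of) if len(sig) else pd.Series(dtype=bool)
    if len(sig) and (~known).any():
        for tgt in sig.loc[~known, "target"].unique():
            logger.warning("aligned target %s missing from cluster table; skipping", tgt)
        sig = sig[known]

    queries = sorted({q for q in alignments["query"]}) if len(alignments) else []
    if motif_runs is None:
        motif_runs = {q: int(q.split("_")[0]) for q in queries}

    rows = {}
    for qname in queries:
        hits = sig[sig["query"] == qname]
        if len(hits):
            best = hits.sort_values(["q", "p", "target"], kind="stable").iloc[0]
            rows[qname] = {"cluster": cluster_of[best["target"]], "target": best["target"],
                           "p": best["p"], "q": best["q"]}
        else:
            rows[qname] = {"cluster": NON_ALIGNED, "target": None, "p": np.nan, "q": np.nan}
    result = pd.DataFrame.from_dict(rows, orient="index")
    result.index.name = "motif"
    result["run"] = [motif_runs.get(q, 0) for q in result.index]

    needed = int(np.ceil(n_models / 2))
    retained_clusters = set()
    for cluster, grp in result[result["cluster"] != NON_ALIGNED].groupby("cluster"):
        if grp["run"].nunique() >= needed:
            retained_clusters.add(cluster)
    result["retained"] = result["cluster"].isin(retained_clusters)
    return result
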