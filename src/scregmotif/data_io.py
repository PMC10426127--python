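"""Readers, writers and encoders for the standard formats the pipeline consumes.

Sequence side: FASTA genomes (via :mod:`pyfaidx`), fixed-width promoter/peak
windows cut around anchor coordinates, one-hot encoding with channel order
A, C, G, T.  Count side: MatrixMarket sparse count matrices with TSV label,
metadata and embedding side files.  Motif side: minimal MEME (version 4)
motif files.

Coordinates are 0-based half-open internally.  Tabular gene/region inputs
default to 1-based anchors (Ensembl-style exports); BED-like input should be
read with ``coord_base=0``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# One-hot encoding
# ---------------------------------------------------------------------------

def one_hot_encode(seq: str) -> np.ndarray:
    """Encode an uppercase DNA string as a 4 x L matrix (rows A, C, G, T).

    ``N`` encodes as an all-zero column; any other character raises
    ``ValueError``.
    """
    arr = np.zeros((4, len(seq)), dtype=np.float32)
    for pos, base in enumerate(seq):
        if base == "N":
            continue
        try:
            arr[_BASE_INDEX[base], pos] = 1.0
        except KeyError:
            raise ValueError(f"invalid nucleotide {base!r} at position {pos}") from None
    return arr


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`; all-zero columns decode to ``N``."""
    if mat.ndim != 2 or mat.shape[0] != 4:
        raise ValueError("expected a 4 x L matrix")
    out = []
    for col in mat.T:
        hit = np.flatnonzero(col)
        out.append("N" if hit.size == 0 else ALPHABET[hit[0]])
    return "".join(out)


# ---------------------------------------------------------------------------
# Sequence containers
# ---------------------------------------------------------------------------

@dataclass
class SequenceSet:
    """Identifier-keyed, equal-length uppercase DNA sequences.

    ``onehot`` is an ``(n, 4, L)`` array in A,C,G,T channel order;
    ``indices`` is the integer encoding (``-1`` for N) used for fast
    nucleotide counting.
    """

    ids: list[str]
    sequences: list[str]
    onehot: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)

    @classmethod
    def from_sequences(cls, ids: list[str], sequences: list[str]) -> "SequenceSet":
        if len(ids) != len(sequences):
            raise ValueError("ids and sequences differ in length")
        if len(set(ids)) != len(ids):
            raise ValueError("sequence ids must be unique")
        lengths = {len(s) for s in sequences}
        if len(lengths) > 1:
            raise ValueError(f"sequences must be equal length, got lengths {sorted(lengths)}")
        onehot = np.stack([one_hot_encode(s) for s in sequences]) if sequences else np.zeros((0, 4, 0), np.float32)
        idx = np.full((len(sequences), len(sequences[0]) if sequences else 0), -1, dtype=np.int8)
        for i, s in enumerate(sequences):
            for j, b in enumerate(s):
                if b != "N":
                    idx[i, j] = _BASE_INDEX[b]
        return cls(ids=list(ids), sequences=list(sequences), onehot=onehot, indices=idx)

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def length(self) -> int:
        return self.onehot.shape[2]

    def subset(self, positions: np.ndarray) -> "SequenceSet":
        positions = np.asarray(positions)
        return SequenceSet(
            ids=[self.ids[i] for i in positions],
            sequences=[self.sequences[i] for i in positions],
            onehot=self.onehot[positions],
            indices=self.indices[positions],
        )

    def to_fasta(self, path) -> None:
        with open(path, "w") as fh:
            for name, seq in zip(self.ids, self.sequences):
                fh.write(f">{name}\n{seq}\n")


def read_fasta_sequences(path) -> SequenceSet:
    """Read an equal-length FASTA into a :class:`SequenceSet`.

    Unlike genome window extraction, N-containing user sequences are kept
    (they encode as zero columns).
    """
    ids: list[str] = []
    seqs: list[str] = []
    current: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if ids:
                    seqs.append("".join(current))
                ids.append(line[1:].split()[0])
                current = []
            else:
                current.append(line.upper())
        if ids:
            seqs.append("".join(current))
    return SequenceSet.from_sequences(ids, seqs)


# ---------------------------------------------------------------------------
# Region tables and window extraction
# ---------------------------------------------------------------------------

@dataclass
class RegionTable:
    """Anchor coordinates (0-based) around which fixed windows are cut.

    For promoters the anchor is the strand-aware transcription start site;
    for peaks, the peak midpoint (odd-length peaks round the midpoint down).
    """

    regions: pd.DataFrame  # columns: chrom, anchor, strand, id
    window_up: int
    window_down: int

    def __post_init__(self) -> None:
        required = {"chrom", "anchor", "strand", "id"}
        missing = required - set(self.regions.columns)
        if missing:
            raise ValueError(f"region table missing columns: {sorted(missing)}")
        if self.regions["id"].duplicated().any():
            raise ValueError("region ids must be unique")
        if (self.regions["anchor"] < 0).any():
            raise ValueError("anchors must be non-negative")
        bad = ~self.regions["strand"].isin(["+", "-"])
        if bad.any():
            raise ValueError(f"invalid strand values: {self.regions.loc[bad, 'strand'].unique()}")


def read_region_table(path, window_up: int, window_down: int, coord_base: int = 1) -> RegionTable:
    """Read a TSV of (chrom, anchor, strand, id).

    ``coord_base=1`` (default) matches Ensembl-style exports; pass 0 for
    BED-like coordinates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str, "id": str})
    rename = {"chromosome": "chrom", "position": "anchor", "name": "id"}
    df = df.rename(columns={k: v for k, v in rename.items() if k in df.columns})
    if coord_base not in (0, 1):
        raise ValueError("coord_base must be 0 or 1")
    df = df.copy()
    df["anchor"] = df["anchor"].astype(int) - coord_base
    return RegionTable(regions=df, window_up=window_up, window_down=window_down)


def extract_window_sequences(genome_path, regions: RegionTable) -> SequenceSet:
    """Cut ``window_up + window_down`` nt windows around each anchor.

    Plus strand: ``[anchor - up, anchor + down)``.  Minus strand: the reverse
    complement of ``[anchor - down, anchor + up)``, so the window is oriented
    5'->3' relative to the feature.  Records that fall outside chromosome
    bounds, hit a missing chromosome, or contain N are dropped with a logged
    warning.
    """
    import pyfaidx

    genome = pyfaidx.Fasta(str(genome_path), as_raw=True, sequence_always_upper=True)
    up, down = regions.window_up, regions.window_down
    width = up + down
    ids: list[str] = []
    seqs: list[str] = []
    for row in regions.regions.itertuples(index=False):
        if row.chrom not in genome:
            logger.warning("chromosome %s not in genome; dropping %s", row.chrom, row.id)
            continue
        chrom_len = len(genome[row.chrom])
        if row.strand == "+":
            start, end = row.anchor - up, row.anchor + down
        else:
            start, end = row.anchor - down, row.anchor + up
        if start < 0 or end > chrom_len:
            logger.warning("window [%d, %d) out of bounds for %s; dropping %s", start, end, row.chrom, row.id)
            continue
        seq = str(genome[row.chrom][start:end])
        if row.strand == "-":
            seq = reverse_complement(seq)
        if "N" in seq:
            logger.warning("window for %s contains N; dropping", row.id)
            continue
        assert len(seq) == width
        ids.append(row.id)
        seqs.append(seq)
    return SequenceSet.from_sequences(ids, seqs)


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse raw counts (features x cells) with per-cell metadata and embedding."""

    values: sparse.csr_matrix
    feature_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame  # index: cell_id; columns include cell_type, batch
    embedding: np.ndarray  # (n_cells, E)

    def __post_init__(self) -> None:
        n_feat, n_cells = self.values.shape
        if len(self.feature_ids) != n_feat:
            raise ValueError("feature_ids length does not match matrix rows")
        if len(self.cell_ids) != n_cells:
            raise ValueError("cell_ids length does not match matrix columns")
        if self.embedding.shape[0] != n_cells:
            raise ValueError("embedding rows do not match number of cells")
        missing = set(self.cell_ids) - set(self.cell_meta.index)
        if missing:
            raise ValueError(f"cell metadata missing {len(missing)} cells, e.g. {sorted(missing)[:3]}")
        if (self.values.data < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    def cell_types(self) -> pd.Series:
        return self.cell_meta.loc[self.cell_ids, "cell_type"]


def read_count_matrix(mtx_path, features_path, cells_path, meta_path, embedding_path) -> CountMatrix:
    """Assemble a :class:`CountMatrix` from MTX + TSV side files.

    ``meta_path`` must have columns ``cell_id``, ``cell_type``, ``batch``;
    ``embedding_path`` has ``cell_id`` plus one column per dimension.
    Dimension mismatches raise an error naming the offending file.
    """
    values = sparse.csr_matrix(spio.mmread(str(mtx_path)))
    feature_ids = pd.read_csv(features_path, sep="\t", header=None)[0].astype(str).tolist()
    cell_ids = pd.read_csv(cells_path, sep="\t", header=None)[0].astype(str).tolist()
    if len(feature_ids) != values.shape[0]:
        raise ValueError(f"{features_path}: {len(feature_ids)} labels for {values.shape[0]} matrix rows")
    if len(cell_ids) != values.shape[1]:
        raise ValueError(f"{cells_path}: {len(cell_ids)} labels for {values.shape[1]} matrix columns")
    meta = pd.read_csv(meta_path, sep="\t", dtype=str).set_index("cell_id")
    missing = set(cell_ids) - set(meta.index)
    if missing:
        raise ValueError(f"{meta_path}: missing metadata for {len(missing)} cells")
    emb = pd.read_csv(embedding_path, sep="\t").set_index("cell_id")
    try:
        embedding = emb.loc[cell_ids].to_numpy(dtype=float)
    except KeyError as exc:
        raise ValueError(f"{embedding_path}: missing embedding rows") from exc
    return CountMatrix(values=values, feature_ids=feature_ids, cell_ids=cell_ids,
                       cell_meta=meta, embedding=embedding)


def write_count_matrix(cm: CountMatrix, out_dir) -> None:
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    spio.mmwrite(str(out / "counts.mtx"), sparse.coo_matrix(cm.values))
    pd.Series(cm.feature_ids).to_csv(out / "features.tsv", sep="\t", header=False, index=False)
    pd.Series(cm.cell_ids).to_csv(out / "cells.tsv", sep="\t", header=False, index=False)
    cm.cell_meta.reset_index().rename(columns={"index": "cell_id"}).to_csv(out / "cell_meta.tsv", sep="\t", index=False)
    emb = pd.DataFrame(cm.embedding, columns=[f"dim{i}" for i in range(cm.embedding.shape[1])])
    emb.insert(0, "cell_id", cm.cell_ids)
    emb.to_csv(out / "embedding.tsv", sep="\t", index=False)


def write_matrix_tsv(matrix, path, row_ids=None, col_ids=None) -> None:
    """Write a labelled dense matrix as a TSV with header row and index column."""
    if isinstance(matrix, pd.DataFrame):
        df = matrix
    else:
        df = pd.DataFrame(np.asarray(matrix), index=row_ids, columns=col_ids)
    df.to_csv(path, sep="\t")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


# ---------------------------------------------------------------------------
# MEME motif files
# ---------------------------------------------------------------------------

def write_meme(motifs: dict[str, np.ndarray], path, pseudocount: float = 0.0) -> None:
    """Write position probability matrices to a minimal MEME (v4) file.

    ``motifs`` maps motif name to a 4 x m PPM (rows A,C,G,T).  A small
    ``pseudocount`` can be added (and renormalized) to avoid exact zeros that
    break some downstream alignment tools; the default writes the PPMs
    verbatim.  Columns that do not sum to 1 within 1e-6 raise ``ValueError``.
    """
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A 0.25000 C 0.25000 G 0.25000 T 0.25000\n\n")
        for name, ppm in motifs.items():
            ppm = np.asarray(ppm, dtype=float)
            if ppm.ndim != 2 or ppm.shape[0] != 4:
                raise ValueError(f"motif {name}: PPM must be 4 x m")
            colsums = ppm.sum(axis=0)
            if np.any(np.abs(colsums - 1.0) > 1e-6):
                raise ValueError(f"motif {name}: PPM columns must sum to 1")
            if pseudocount > 0:
                ppm = (ppm + pseudocount) / (1.0 + 4 * pseudocount)
            fh.write(f"MOTIF {name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {ppm.shape[1]} nsites= 20 E= 0\n")
            for col in ppm.T:  # MEME rows are positions
                fh.write(" ".join(f"{v:.6f}" for v in col) + "\n")
            fh.write("\n")


def read_meme(path) -> dict[str, np.ndarray]:
    """Parse a minimal MEME motif file into name -> 4 x m PPM."""
    motifs: dict[str, np.ndarray] = {}
    name = None
    rows: list[list[float]] = []
    expecting = 0
    with open(path) as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.startswith("MOTIF"):
                parts = stripped.split()
                name = parts[1]
                rows = []
                expecting = 0
            elif stripped.startswith("letter-probability matrix"):
                tokens = stripped.replace("=", " = ").split()
                expecting = int(tokens[tokens.index("w") + 2])
            elif expecting and stripped and stripped[0] in "0123456789.":
                rows.append([float(v) for v in stripped.split()])
                if len(rows) == expecting:
                    motifs[name] = np.array(rows).T  # back to 4 x m
                    expecting = 0
    return motifs


# ---------------------------------------------------------------------------
# Gene sets and cluster tables
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: set name, description, then member genes."""
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def read_cluster_table(path) -> pd.DataFrame:
    """Read a TSV mapping motif/TF ids to motif cluster names.

    Expects columns ``id`` and ``cluster``; every id must map to exactly one
    cluster.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"id", "cluster"}.issubset(df.columns):
        raise ValueError("cluster table needs columns 'id' and 'cluster'")
    if df["id"].duplicated().any():
        raise ValueError("cluster table ids must be unique")
    return df
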