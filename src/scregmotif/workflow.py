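"""Pipeline orchestration: simulate -> pool -> train -> motifs -> influence.

A YAML config drives the run; every stage writes its outputs under the run
directory and records a content hash (stage config + upstream hashes) in
``manifest.json``, so re-running with an unchanged config skips completed
stages and changing one stage's parameters recomputes only it and its
downstream dependents.  One global seed fans out per stage as
``seed + stage_index``.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scregmotif import data_io
from scregmotif.influence import aggregate_influence, ensemble_influence, z_transform
from scregmotif.motif_discovery import align_motifs, assign_clusters, extract_ensemble_pfms
from scregmotif.network import Checkpoint, ModelConfig
from scregmotif.pooling import PoolingConfig, geometric_sketch, pool_cells
from scregmotif.synthetic_data import SimulationConfig, simulate_dataset
from scregmotif.training import HyperPriors, align_inputs, train_ensemble

logger = logging.getLogger(__name__)

STAGES = ["simulate", "pool", "train", "motifs", "influence"]

_ALLOWED_KEYS = {
    "seed": None,
    "out_dir": None,
    "simulate": {"n_sequences", "L", "planting_prob", "gc", "n_cells", "n_celltypes",
                 "n_pools", "pool_size", "baseline", "noise_sd"},
    "pool": {"n_pools", "pool_size", "include_seed"},
    "train": {"d", "m", "folds", "epochs", "lr", "sigma_motifs", "sigma_net",
              "batch_size", "calibrations"},
    "motifs": {"database", "clusters", "threshold", "tomtom_path"},
    "influence": {"z"},
}


def validate_config(config: dict) -> None:
    bad = []
    for key, value in config.items():
        if key not in _ALLOWED_KEYS:
            bad.append(key)
        elif _ALLOWED_KEYS[key] is not None and isinstance(value, dict):
            bad.extend(f"{key}.{sub}" for sub in value if sub not in _ALLOWED_KEYS[key])
    if bad:
        raise ValueError(f"unknown config keys: {sorted(bad)}")


def _hash(obj) -> str:
    return hashlib.sha256(json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


class _Manifest:
    def __init__(self, path: Path):
        self.path = path
        self.data = json.loads(path.read_text()) if path.exists() else {}

    def fresh(self, stage: str, digest: str, outputs: list[Path]) -> bool:
        entry = self.data.get(stage)
        return (entry is not None and entry["hash"] == digest
                and all(Path(p).exists() for p in entry["outputs"]))

    def record(self, stage: str, digest: str, outputs: list[Path], elapsed: float) -> None:
        self.data[stage] = {"hash": digest, "outputs": [str(p) for p in outputs],
                            "seconds": round(elapsed, 2)}
        self.path.write_text(json.dumps(self.data, indent=2))


def run_pipeline(config_path, log=print) -> Path:
    """Execute the configured stages in order; returns the run directory."""
    config = yaml.safe_load(Path(config_path).read_text()) or {}
    validate_config(config)
    seed = int(config.get("seed", 0))
    out = Path(config.get("out_dir", "scregmotif_run"))
    out.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(out / "manifest.json")

    upstream = ""
    state: dict = {}
    for stage_index, stage in enumerate(STAGES):
        stage_cfg = config.get(stage, {}) or {}
        digest = _hash({"stage": stage, "config": stage_cfg, "upstream": upstream, "seed": seed})
        stage_dir = out / stage
        runner = globals()[f"_stage_{stage}"]
        stage_seed = seed + stage_index
        if manifest.fresh(stage, digest, []):
            log(f"[{stage}] up to date, skipping")
            state = runner(stage_cfg, stage_dir, stage_seed, state, load_only=True)
        else:
            t0 = time.time()
            stage_dir.mkdir(parents=True, exist_ok=True)
            state = runner(stage_cfg, stage_dir, stage_seed, state, load_only=False)
            manifest.record(stage, digest, sorted(stage_dir.glob("*")), time.time() - t0)
            log(f"[{stage}] done in {time.time() - t0:.1f}s (seed {stage_seed})")
        upstream = digest
    (out / "run_log.json").write_text(json.dumps(
        {"seed": seed, "stages": manifest.data}, indent=2))
    return out


# ---------------------------------------------------------------------------
# Stage implementations (each returns the accumulated pipeline state)
# ---------------------------------------------------------------------------

def _stage_simulate(cfg: dict, stage_dir: Path, seed: int, state: dict, load_only: bool) -> dict:
    sim_config = SimulationConfig(rng_seed=seed, **cfg)
    ds = simulate_dataset(sim_config)  # deterministic: regenerate instead of reloading
    if not load_only:
        ds.sequences.to_fasta(stage_dir / "sequences.fa")
        ds.truth.instances.to_csv(stage_dir / "truth_instances.tsv", sep="\t", index=False)
        data_io.write_count_matrix(ds.counts, stage_dir / "counts")
        data_io.write_meme({f"M{i}": p for i, p in enumerate(sim_config.motif_ppms)},
                           stage_dir / "true_motifs.meme")
        pd.DataFrame({"id": [f"M{i}" for i in range(sim_config.n_motifs)],
                      "cluster": [f"M{i}" for i in range(sim_config.n_motifs)]}).to_csv(
            stage_dir / "true_clusters.tsv", sep="\t", index=False)
    state.update(dataset=ds, sim_config=sim_config)
    return state


def _stage_pool(cfg: dict, stage_dir: Path, seed: int, state: dict, load_only: bool) -> dict:
    ds = state["dataset"]
    pconf = PoolingConfig(
        n_pools=cfg.get("n_pools", ds.config.n_pools),
        pool_size=cfg.get("pool_size", ds.config.pool_size),
        include_seed=cfg.get("include_seed", True),
        rng_seed=seed,
    )
    rng = np.random.default_rng(seed)
    seeds = geometric_sketch(ds.counts.embedding, pconf.n_pools, rng)
    pooled = pool_cells(ds.counts, seeds, pconf)
    if not load_only:
        data_io.write_matrix_tsv(pooled.to_frame(), stage_dir / "pooled.tsv")
        pd.DataFrame({"pool_id": pooled.pool_ids, "cell_type": pooled.pool_celltype,
                      "purity": pooled.pool_purity}).to_csv(
            stage_dir / "pool_annotation.tsv", sep="\t", index=False)
    state["pooled"] = pooled
    return state


def _stage_train(cfg: dict, stage_dir: Path, seed: int, state: dict, load_only: bool) -> dict:
    ds, pooled = state["dataset"], state["pooled"]
    seqs, targets = align_inputs(ds.sequences, pooled)
    folds = cfg.get("folds", 3)
    model_config = ModelConfig(d=cfg.get("d", 50), m=cfg.get("m", 12),
                               p=targets.shape[1], L=seqs.length)
    if load_only:
        checkpoints = [Checkpoint.load(p) for p in sorted(stage_dir.glob("fold_*.npz"))]
        state.update(checkpoints=checkpoints, train_sequences=seqs, train_targets=targets)
        return state
    rng = np.random.default_rng(seed)
    epochs = cfg.get("epochs", 40)
    if "calibrations" in cfg:
        priors = HyperPriors(epochs=epochs, num_calibrations=cfg["calibrations"])
        ensemble = train_ensemble(seqs, targets, model_config, K=folds, epochs=epochs,
                                  rng=rng, priors=priors)
    else:
        hp = {"lr": cfg.get("lr", 2e-2), "sigma_motifs": cfg.get("sigma_motifs", 1e-4),
              "sigma_net": cfg.get("sigma_net", 1e-3), "batch_size": cfg.get("batch_size", 64)}
        ensemble = train_ensemble(seqs, targets, model_config, K=folds, epochs=epochs,
                                  rng=rng, hyperparams=hp)
    for k, ckpt in enumerate(ensemble.checkpoints):
        ckpt.save(stage_dir / f"fold_{k}.npz")
    ensemble.metrics.to_csv(stage_dir / "metrics.tsv", sep="\t", index=False)
    state.update(checkpoints=ensemble.checkpoints, train_sequences=seqs, train_targets=targets)
    return state


def _stage_motifs(cfg: dict, stage_dir: Path, seed: int, state: dict, load_only: bool) -> dict:
    motifs = extract_ensemble_pfms(state["checkpoints"], state["train_sequences"])
    db_path = cfg.get("database") or stage_dir.parent / "simulate" / "true_motifs.meme"
    clusters_path = cfg.get("clusters") or stage_dir.parent / "simulate" / "true_clusters.tsv"
    database = data_io.read_meme(db_path)
    alignments = align_motifs(motifs, database, threshold=cfg.get("threshold", 0.05),
                              rng=np.random.default_rng(seed),
                              tomtom_path=cfg.get("tomtom_path"))
    assignment = assign_clusters(alignments, data_io.read_cluster_table(clusters_path),
                                 n_models=len(state["checkpoints"]))
    if not load_only:
        motifs.write_meme(stage_dir / "motifs.meme")
        alignments.to_csv(stage_dir / "alignments.tsv", sep="\t", index=False)
        assignment.to_csv(stage_dir / "assignment.tsv", sep="\t")
    state.update(motifs=motifs, alignments=alignments, assignment=assignment)
    return state


def _stage_influence(cfg: dict, stage_dir: Path, seed: int, state: dict, load_only: bool) -> dict:
    pooled = state["pooled"]
    infl = ensemble_influence(state["checkpoints"], state["train_sequences"])
    infl.columns = pooled.pool_ids[:infl.shape[1]]
    agg = aggregate_influence(infl, pooled.pool_celltype, state["assignment"])
    if not load_only:
        data_io.write_matrix_tsv(infl, stage_dir / "influence_motif_pool.tsv")
        data_io.write_matrix_tsv(agg, stage_dir / "influence_cluster_celltype.tsv")
        if cfg.get("z", True):
            data_io.write_matrix_tsv(z_transform(agg), stage_dir / "influence_cluster_celltype_z.tsv")
    state["influence"] = {"motif_pool": infl, "cluster_celltype": agg}
    return state
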