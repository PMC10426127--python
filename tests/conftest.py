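"""Shared fixtures: the flagship end-to-end synthetic run and small helpers."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from scregmotif.influence import aggregate_influence, ensemble_influence
from scregmotif.motif_discovery import align_motifs, assign_clusters, extract_ensemble_pfms
from scregmotif.network import ModelConfig
from scregmotif.synthetic_data import SimulationConfig, simulate_dataset
from scregmotif.training import train_ensemble

FLAGSHIP_HYPERPARAMS = {"lr": 2e-2, "sigma_motifs": 1e-4, "sigma_net": 1e-3, "batch_size": 64}


@pytest.fixture(scope="session")
def flagship():
    """One full pipeline run on the default synthetic study conditions.

    2000 sequences of 200 nt with 5 planted 12-nt motifs, 50 pools over 4
    cell types, d=50 filters, 3 cross-validation folds.  Training, motif
    extraction, alignment against the true planted motifs, and influence
    aggregation are shared by the integration-level tests.
    """
    config = SimulationConfig(rng_seed=1)
    ds = simulate_dataset(config)
    targets = ds.pooled.values
    model_config = ModelConfig(d=50, m=12, p=targets.shape[1], L=config.L)
    ensemble = train_ensemble(ds.sequences, targets, model_config, K=3, epochs=40,
                              rng=np.random.default_rng(0),
                              hyperparams=dict(FLAGSHIP_HYPERPARAMS))
    motifs = extract_ensemble_pfms(ensemble.checkpoints, ds.sequences)
    true_motifs = {f"M{i}": ppm for i, ppm in enumerate(config.motif_ppms)}
    alignments = align_motifs(motifs, true_motifs, rng=np.random.default_rng(2))
    cluster_table = pd.DataFrame({"id": list(true_motifs), "cluster": list(true_motifs)})
    assignment = assign_clusters(alignments, cluster_table, n_models=ensemble.K)
    influence = ensemble_influence(ensemble.checkpoints, ds.sequences)
    cluster_celltype = aggregate_influence(influence, ds.pooled.pool_celltype, assignment)
    return {
        "config": config,
        "dataset": ds,
        "targets": targets,
        "ensemble": ensemble,
        "motifs": motifs,
        "true_motifs": true_motifs,
        "alignments": alignments,
        "assignment": assignment,
        "influence": influence,
        "cluster_celltype": cluster_celltype,
    }


@pytest.fixture()
def toy_genome(tmp_path):
    """A two-chromosome FASTA small enough to reason about by hand."""
    path = tmp_path / "genome.fa"
    path.write_text(">chr1\nACGTACGTACGTACGTACGT\n>chrN\nACGTNNGTACGTACGTACGT\n")
    return path
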