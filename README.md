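# scregmotif

De novo discovery of regulatory sequence motifs and quantification of their
per-cell-type influence on gene expression or chromatin accessibility from
single-cell data.

Identifying which transcription-factor binding motifs are functional — and
how much each one matters in each cell type — is hard because most motifs
are degenerate and single-cell measurements are sparse. scregmotif addresses
both problems at once: raw counts are pooled over k-nearest-neighbour
groups of cells to produce dense per-pool activity profiles, and a shallow
convolutional network is trained to predict those profiles directly from
the one-hot encoded regulatory sequences (promoter windows or ATAC peaks).
Because the network has exactly one convolutional layer, every filter is
interpretable as a sequence motif, and a leave-one-out ablation gives each
motif a quantitative influence score per pool and per cell type.

It is aimed at computational biologists who have a single-cell count matrix
(RNA or ATAC), a low-dimensional embedding of the cells, and a genome, and
who want a ranked, cell-type-resolved list of candidate motifs and TFs.

## Model

For a one-hot sequence `x` (4 × L, channels A,C,G,T) the model computes

    a_i = max_pos ELU( F_i · x[:, pos:pos+m] )        d filters, width m
    ŷ   = a W + b                                      readout to p pools

trained with MSE and Adam under K-fold nested cross-validation, with
log-uniform hyperparameter priors winnowed by successive halving and
patience-1 early stopping. Each filter i is converted to a position
frequency matrix from its max-activating subsequences, aligned to a motif
database (Tomtom when installed, a built-in PPM comparator otherwise), and
assigned to a motif cluster. The influence of motif i on pool j is

    n_ij = (1/N) Σ_k ( b_ijk − c_ijk )

the mean prediction drop over validation sequences when all parameters of
filter i are zeroed; influences are averaged over pools per cell type and
summed over motifs per reproducible cluster (a cluster counts only if it
appears in at least half of the K fold models).

See `docs/methods.md` for assumptions, parameter defaults, and limitations.

## Worked example

The built-in generator plants five known 12-nt motifs into 2000 synthetic
promoter sequences with cell-type-specific effect sizes, so every stage can
be checked against ground truth:

```python
import numpy as np
from scregmotif import ModelConfig, SimulationConfig, simulate_dataset
from scregmotif.training import train_ensemble
from scregmotif.motif_discovery import extract_ensemble_pfms, align_motifs, assign_clusters
from scregmotif.influence import ensemble_influence, aggregate_influence
import pandas as pd

ds = simulate_dataset(SimulationConfig(rng_seed=1))
targets = ds.pooled.values                       # 2000 sequences x 50 pools
config = ModelConfig(d=50, m=12, p=targets.shape[1], L=ds.config.L)
ens = train_ensemble(ds.sequences, targets, config, K=3, epochs=40,
                     rng=np.random.default_rng(0),
                     hyperparams={"lr": 2e-2, "sigma_motifs": 1e-4,
                                  "sigma_net": 1e-3, "batch_size": 64})
print(ens.metrics[["fold", "r2", "r2_scrambled_sequences", "r2_permuted_pools"]])

motifs = extract_ensemble_pfms(ens.checkpoints, ds.sequences)
true = {f"M{i}": p for i, p in enumerate(ds.config.motif_ppms)}
aln = align_motifs(motifs, true, rng=np.random.default_rng(2))
assign = assign_clusters(aln, pd.DataFrame({"id": list(true), "cluster": list(true)}),
                         n_models=3)
infl = aggregate_influence(ensemble_influence(ens.checkpoints, ds.sequences),
                           ds.pooled.pool_celltype, assign)
print(infl.round(2))
```

Output (abridged):

```
 fold       r2  r2_scrambled_sequences  r2_permuted_pools
    0 0.710468                0.003824           0.235475
    1 0.696783                0.004698           0.250149
    2 0.677679                0.002677           0.188270

    type_0  type_1  type_2  type_3
M0    6.45    1.66   -0.16   -0.17
M1    0.25    6.60    1.69   -0.04
M2    0.22   -0.11    6.06    1.62
M3    1.96    0.00    0.03    6.62
M4    5.90    1.58   -0.05   -0.01
```

The model explains ~70% of held-out variance; scrambling nucleotides (which
destroys motifs) or permuting pool order (which destroys cell-type
structure) collapses it. Each planted motif's cluster shows its largest
influence in the cell type where the simulation gave it effect 2.0, its
secondary influence where it gave 0.5, and ~0 elsewhere — the influence
matrix recovers the planted effect matrix (Spearman ρ ≈ 0.92).

## Command line

`scregmotif` exposes each stage (`simulate`, `pool`, `train`, `motifs`,
`influence`, `analyze tf-corr|gene-sets|motif-space|co-occurrence|signature`)
and a `run` command that executes a whole YAML-configured pipeline with a
content-hash manifest so unchanged stages are skipped on rerun:

```sh
scregmotif run --config pipeline.yaml
```

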