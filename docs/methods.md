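# Methods

## Model

scregmotif models the activity of a regulatory sequence (a promoter window
or an open-chromatin peak) across cell pools as a linear function of motif
match scores discovered de novo. For one-hot encoded sequence `x` (channels
A, C, G, T), the prediction for the `p` pools is

    a_i(x) = max_pos ELU( sum_{j,c} F_i[j,c] * x[c, pos+j] )      i = 1..d
    y(x)   = a(x) W + b                                            W: d x p

with `d` convolutional filters `F_i` of width `m` (defaults d = 600,
m = 12; the synthetic study runs use d = 50), no convolutional bias, valid
padding, stride 1, forward strand only, and a fully connected readout with
bias. The ELU (alpha = 1) bounds pooled activations below by −1; the global
max pool makes `a_i` the best match of filter i anywhere in the sequence,
so a filter is interpretable as one motif and the bias absorbs
sequence-independent determinants of activity. Max-pool argmax ties break
at the lowest position so motif extraction is deterministic.

The forward pass and analytic gradients are implemented directly on NumPy
arrays (an im2col unfolding turns every convolution into one BLAS matmul).
At this depth that is faster to audit than a framework graph and keeps the
argmax bookkeeping — which motif extraction and the gradient routing both
depend on — explicit.

## Pooling

Raw single-cell counts are summed over the k-nearest neighbours (Euclidean,
in a user-supplied low-dimensional embedding) of seed cells chosen by
covering-grid sampling: binary-search a hypercube side length until the
number of occupied cubes reaches the requested pool count, then draw one
cell per occupied cube. Sampling per unit of occupied volume rather than
per cell preserves rare populations. Each pool holds exactly `q` cells
(seed + q−1 neighbours; `include_seed=False` switches to the q nearest
non-seed cells for compatibility with tools that count the seed
separately). Pooled values are `log(1 + sum of raw counts)` (natural log);
each pool is annotated with its modal member cell type (ties break
lexicographically, logged) and the modal fraction as purity.

Feature filtering presets mirror common single-cell recipes: drop features
detected in fewer than `min_detect_frac` of pools, and keep features below
a second `rescue_frac` only if their mean non-zero value exceeds a rescue
threshold. The rescue thresholds are applied as the literal constants
log10(3) / log10(4) against the natural-log pooled values; the numeric
constants, not a log-base conversion, define the presets.

## Training

Sequences are split into K outer folds (default 10; 3 in the synthetic
study). Each fold's held-out 10% is the outer test set; the remaining
"inner" 90% splits 80/20 into training and validation. One model is
trained per fold, so the ensemble size r equals K.

Hyperparameters are drawn from the priors: learning rate log-uniform on
[5e-4, 5e-2], filter-init scale sigma_motifs log-uniform on [1e-7, 1e-3],
readout-init scale sigma_net log-uniform on [1e-5, 1e-2], batch size
uniform on {64, 128, 256, 512}. Candidates are winnowed by synchronous
successive halving (eta = 3, 3 rungs): all candidates train at ~1/9 of the
epoch budget, the top third at ~1/3, the top ninth at the full budget, and
the configuration with the lowest observed inner-validation MSE wins. We
use random draws from the stated priors rather than a Bayesian proposal
mechanism; at this budget the selection behaviour is equivalent and the
procedure is exactly reproducible from one seed.

Final training minimizes MSE with Adam (0.9/0.999, eps 1e-8), evaluates
inner-validation MSE after every epoch, stops at the first epoch with no
improvement over the best so far (patience 1), and returns the parameters
of the best epoch. Filters start near zero (sigma_motifs ~ 1e-4) so only
motifs the data supports grow; readout biases start at 1e-5.

Held-out quality is the squared Pearson correlation between predicted and
observed values per pool, averaged over pools. Two negative controls
accompany every evaluation: permuting the nucleotides of each held-out
sequence (destroys motifs, preserves composition) and permuting the pool
order of the observed targets (destroys pool-specific structure). A model
that has learned sequence- and cell-type-specific signal must beat both.

## Motifs and influence

For each filter, the width-m window with the highest positive post-ELU
activation in each training sequence contributes its nucleotides to the
filter's PFM; sequences with no positive activation are excluded, so PFM
column sums equal the number of contributing sequences and the PPM is the
plain column-normalized PFM (no pseudocount; a 1e-4 pseudocount is added
only when writing MEME files so downstream tools never see exact zeros).

Filters are aligned to a motif database with Tomtom (`-thresh 0.05`) when
the executable is available. Otherwise a built-in comparator scores the
best mean per-column Pearson correlation over all ungapped offsets and
both orientations, with an empirical p-value from 1000 column-shuffled
versions of the query and BH correction across pairs. The minimum overlap
defaults to two thirds of the shorter motif: short chance overlaps of
near-one-hot columns score deceptively well under the shuffle null.
Each filter takes the cluster of its most significant alignment (lowest q,
ties by p then target id); a cluster is reproducible only if it contains
filters from at least ceil(K/2) of the K models.

The influence of filter i on pool j is n_ij = mean_k (b_ijk − c_ijk) over
the model's validation sequences, where c is the prediction with all of
filter i's parameters (conv weights and readout row) zeroed. Because the
readout is linear and a zeroed filter yields ELU(0) = 0, this equals
W_ij · mean_k a_ik exactly; the test suite checks the implementation
against a brute-force model-rebuild oracle as well as this closed form.
Influences from the K models stack into dK rows, are averaged over pools
per cell type and summed over motifs per reproducible cluster.
Z-transformed views use the population SD per row; constant rows map to
zeros (with a warning) rather than NaN.

## Downstream analyses

All associations use Spearman correlation across pools (large-sample
p-values) with BH correction where many pairs are tested. Candidate TFs
for a cluster are ranked by the correlation between cluster influence and
TF expression. Gene sets of fewer than 50 genes are summarized as the mean
member expression per pool and correlated with each cluster's influence;
the top 500 sets by maximum correlation (the count is the default, a
fraction is available) are hierarchically clustered with average linkage on
Euclidean distance and cut into 3 groups. The "motif space" matrix
concatenates per-sequence post-ELU max-pooled activations run-major across
the ensemble (n_sequences × r·d); family scores sum member-filter columns,
and a gene carries a family when its score exceeds 75% of the family's
maximum. Signature scores are mean pooled expression of a gene list.
Embedding computation (UMAP/PCA of cells or of motif space) and trajectory
inference are consumed as inputs, never computed here.

## Synthetic study conditions

The generator plants `n_motifs` PWM instances (default: five sharp 12-nt
motifs, dominant base probability 0.88) independently with probability 0.3
per (sequence, motif) at non-overlapping uniform positions in 2000
i.i.d.-background sequences of 200 nt (GC 0.5). A sequence's expected
value in a pool of cell type t is `1.0 + counts · W[:, t]` on the pooled
log scale, with the default effect matrix giving each motif one dominant
cell type (effect 2.0) and one secondary (0.5) among 4 types — effects
well above the Gaussian target noise (SD 0.1). 500 cells sit in four
well-separated Gaussian blobs (centres on a circle of radius 10, SD 0.5)
in a 2-D embedding, and per-cell counts are Poisson with rates
`expm1(expected)/q`, so pooling q = 10 same-type cells recovers the
expected values in expectation; 50 pools cover the four types.

These conditions emulate the structure, not the messiness, of real data:
no batch effects, no dropout beyond Poisson sampling, no correlated motif
co-occurrence, balanced cell types, and an embedding in which types are
perfectly separable. Passing tests therefore demonstrate correctness of the
machinery and recoverability under clear signal, not performance on real
tissues. Problem sizes (2000 × 200 nt, d = 50, 3 folds) were chosen so the
whole study runs in seconds on one CPU while leaving each fold ~1400
training sequences — enough for the patience-1 early stopping to act on a
smoothly decreasing validation curve.

## Numerical choices and limitations

- Conv/readout math in float64; ELU via `expm1` for accuracy at large
  negative pre-activations.
- The fixed training configuration used by the synthetic study (lr 2e-2,
  sigma_motifs 1e-4, sigma_net 1e-3, batch 64) lies inside the search
  priors; the full successive-halving search is available and tested but
  not exercised in the default study to keep it fast.
- Patience-1 early stopping is aggressive by design; on very small
  datasets (few hundred sequences) the per-epoch validation MSE is noisy
  enough to stop training prematurely. The study conditions avoid this by
  scale; real datasets in the method's intended regime are larger still.
- Forward-strand scanning only; motifs on the reverse strand are learned
  as their reverse complements.
- The built-in PPM comparator is a pragmatic stand-in for Tomtom's exact
  null; its empirical p-values are resolution-limited by the 1000 shuffles.
- Peak midpoints for even/odd peak widths round down.
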