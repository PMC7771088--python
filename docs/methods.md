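# Methods

This note records the models implemented in `netdrug`, the assumptions
they make, the defaults and why, and what the synthetic benchmarks do and
do not establish.

## Data model and preprocessing

Inputs are a gene × cell-line expression matrix `X` (delimited text,
first column gene ids, header sample ids, `NA`/empty = missing) and a
drug × cell-line response table (AUC or ED50).  Expression values are
used as supplied — no log transform or normalization is applied, and the
choice of input scale is the caller's; all network quantities are
correlation-based and therefore invariant to per-gene affine rescaling.

Preprocessing applies four rules, in order:

1. **Expression/variance filter.**  Genes whose mean expression or
   variance fall below configurable quantiles of the gene-wise
   distributions are dropped (defaults 0.2 / 0.2).  The cleaning rule is
   standard for cell-line screens but has no canonical cutoffs, so both
   are exposed as parameters.  Because the thresholds are quantiles of
   the current input, re-applying the filter to its own output can remove
   further genes; idempotence holds for the value-based rules below but
   not for this rank-based one — a documented limitation of quantile
   thresholds.
2. **Imputation.**  A gene numeric in strictly more than 90% of samples
   has missing entries replaced by its mean over numeric entries;
   any other gene with a missing value is dropped.  Mean imputation
   preserves each retained gene's mean exactly and shrinks its variance
   slightly.
3. **Drug mode filter.**  A drug whose single most frequent response
   value covers strictly more than 80% of cell lines is dropped (assay
   saturation).  The mode is counted by exact float equality: the rule
   targets literally repeated assay values, so no tolerance is applied.
4. **Alignment.**  Both tables are restricted to shared samples in the
   expression matrix's column order.

## Co-expression network

`A_ij = |pearson(x_i, x_j)|` with `A_ii = 0`.  Zeroing the diagonal
before any normalization avoids double-counting self-loops when the
graph-convolution operator later adds the identity.  Three operators are
derived:

* `S = D^{-1/2} A D^{-1/2}` with `D = diag(row sums of A)`;
* `L = I − S`, symmetric positive semidefinite with spectrum in [0, 2];
* `P = D̃^{-1/2} (A + I) D̃^{-1/2}` with `D̃ = diag(column sums of A + I)`.

Computing `D̃` from `A + I` (rather than from `A` alone) is deliberate:
degrees of the self-loop-free graph would be zero for an isolated gene,
and the renormalized form is what gives `P` its unit spectral bound.
`A` is kept dense — after feature selection the gene count is moderate —
with an optional sparsification threshold, off by default.

## Network-propagation feature selection

Initial scores `c_i = |corr(x_i, y)|` are smoothed by minimizing
`J(f) = α fᵀLf + (1−α)‖f−c‖²`.  The closed-form minimizer
`f = (1−α)(I−αS)^{-1}c` is used up to 5 000 genes; beyond that the
fixed-point iteration `f ← αSf + (1−α)c` runs to an ∞-norm change below
1e−8 (at most 1 000 sweeps).  The two paths agree to well under 1e−6 and
are cross-validated in the test suite against a generic quasi-Newton
minimizer of `J`.  Since `‖αS‖ < 1`, the Neumann series of `(I−αS)^{-1}`
is nonnegative, which makes `f` monotone in `c` — verified empirically.

`α` (default 0.5) trades fidelity to the marginal scores against network
smoothness; there is no canonical value, and it is exposed everywhere.
Top-k ties break toward the lexicographically smaller gene id for
reproducibility.  Within the benchmark the network is rebuilt from the
training samples of every split, so selection can never see test data.

## Neighborhood embedding

Each gene's neighborhood is its top-3 correlated genes plus the top-3 of
each of those.  Second-order candidates that repeat the target, a
first-order neighbor, or each other are deduplicated (the construction
yields nine distinct second-order genes exactly when no overlaps occur);
correlation ties break lexicographically.  The layer update

`e_v^k = σ(W_k · mean_{u∈N(v)} e_u^{k−1} + e_v^{k−1})`,  `e_v^0 = x_v`

uses one weight matrix per layer shared by all genes: per-gene weights
with sample-dimension embeddings would add `m·n²` parameters against a
few hundred samples.  The reconstruction loss sums
`(z_vᵀz_u − A_vu)²` over all (target, neighbor) pairs.

Two numerical choices matter.  First, the initial embeddings are the
z-scored expression rows divided by √n (configurable off), so initial
inner products equal signed Pearson correlations — the same scale as the
adjacency entries being reconstructed; with raw expression the loss
starts many orders of magnitude off-scale and gradients are badly
conditioned.  Second, the default activation is tanh (bounded, keeps
inner products near the adjacency's range); ReLU and identity are
available.  Training is full-batch Adam, lr 1e−3, 200 epochs by default.

Because `W_k` acts on the sample axis, the embedding transform is
inherently transductive: it is computed on the full expression matrix,
while its reconstruction target `A` comes from training samples only and
every supervised step (feature selection, the fully connected head) sees
the training partition alone.  Response labels never enter the
embedding, so the test-label poisoning audit passes by construction; the
use of unlabeled test-sample expression is the one semi-supervised
element of this model and is stated here explicitly.

The prediction head selects `k` features from the embedding matrix and
`k` from the expression matrix (default 100 each, by training-partition
correlation), concatenates them, z-scores by training statistics, and
fits a one-hidden-layer ReLU network on MSE.

## Graph convolutional regressor

Each cell line is one signal on the gene graph: `H^0` holds the per-gene
expression scalars, and `H^k = σ(P H^{k−1} W^{k−1})` widens the feature
axis (defaults: two layers of width 64, ReLU).  Samples are the batch
dimension.  By default the GCN consumes the genes selected by the
network method, matching the shared evaluation protocol; an all-genes
mode is available.

The readout head is a learned linear map on the gene-averaged final
features (`mean_pool`).  A per-gene learned linear head (`linear`) is
also provided, but on panels of a few hundred samples it overfits
measurably — on the standard synthetic setting (n = 200, signal-to-noise
5, selected genes) mean held-out r over 10 seeds is 0.894 for mean-pool
against 0.765 for the per-gene head, with a noise ceiling of 0.913 —
so mean-pool is the default.  Inputs are z-scored and the response
centred by training-sample statistics (configurable), which leaves
correlations untouched and conditions the optimization.  Training is
full-batch Adam (lr 1e−2, 300 epochs); fixed seeds give bit-identical
runs.  Checkpoints serialize to a JSON manifest of weights plus config.

All neural components (embedding, GCN, DNN baseline) are plain NumPy
with hand-derived gradients and a shared Adam implementation; they are
deliberately small, full-batch, and deterministic.

## Baselines

Fixed hyperparameters, no validation-set tuning: Random Forest in
regression mode (500 trees, 50 candidate split features), Elastic Net
(l1 ratio 0.5, penalty 0.1 — the penalty strength has no fixed canonical
value and is configurable), SVR (RBF, C = 1, γ = 1/(p·Var(X)), ε = 0.1),
PLSR with one latent component, and a two-hidden-layer ReLU DNN trained
on MSE.  A softmax output unit for the DNN is available for comparison
runs but is degenerate for scalar regression — it emits the constant 1 —
so the regression default is a linear output unit.

## Evaluation protocol

`floor(0.7·n)` samples train, the rest test, re-drawn `n_repeats` times
from a base seed; the identical split list serves every method.  Scores
are Pearson r between predicted and true response on the test samples;
cells with constant predictions are undefined, logged, and excluded from
means.  Grand means average all (drug, repeat) cells per method ×
selector; per-drug tables average over repeats.  Method pairs are
compared by a two-sided Wilcoxon signed-rank over matched cells —
a robust default since per-cell correlations are bounded and skewed —
with a paired t-test available.  Per-cell failures are caught, recorded
in the report's `error` column, and do not stop the run.

## Synthetic generator

Gene `i` of module `j` is `√ρ·t_j + √(1−ρ)·ε`, giving exact pairwise
population correlation ρ within the module; background genes are
independent noise; per-gene means (uniform 4–8) and scales (0.5–2) give
the expression filter something to act on without touching correlations.
Each drug's response is `effect·t_causal + N(0, noise²)`, so the
signal-to-noise variance ratio is `(effect/noise)²` and the best
achievable test correlation is `√(snr/(1+snr))`.  Defaults mirror the
standard study conditions used throughout the tests: 500 cell lines, 200
genes, five 10-gene modules, ρ = 0.8, signal-to-noise 5.  Missing
entries are injected completely at random.

What the generator does **not** emulate: count-distributed RNA-seq noise,
batch effects, correlated missingness, overlapping modules, nonlinear
gene–response links.  Passing tests therefore establish correctness of
the machinery and recovery of linear modular signal, not performance on
real screens.

One empirical boundary is worth stating: when the signal-to-noise is
high and samples are plentiful, marginal correlations already rank the
causal module perfectly and network propagation can only tie, not beat,
the correlation ranking (mean causal rank is invariant to permutations
within the top-k).  The advantage of propagation appears exactly where
it is claimed to: in the noisy regime (few samples, weak effects), where
it strictly improves causal-gene ranks in ~95% of simulated panels.

## Problem sizes

The test suite and `scripts/acceptance.py` run on panels of 40–500
cell lines and 13–200 genes, with 5–20 seeds or repeats per property —
sizes at which every contract is exercised end-to-end in well under a
minute each on a single core.
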