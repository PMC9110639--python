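# Methods

## Dropout model

Dropout probability for an entry with observed expression level *s* is
modelled as the Michaelis–Menten complement `P(s) = 1 − s/(K_M + s)`:
saturating enzyme kinetics for the reverse-transcription step, appropriate
for full-transcript protocols and TPM-normalized values, not for
RPKM/FPKM-normalized data or UMI-based droplet data (the imputer warns when
the value distribution looks RPKM/FPKM-like, i.e. >20% of nonzeros below 1).

A single global `K_M` is fitted by bounded 1-D least squares of each gene's
zero fraction `d_g` against `K_M/(K_M + m_g)`, where `m_g` is the gene's
mean expression over all cells, zeros included. A per-gene constant would be
over-parameterized for its only purpose here — loss weighting — and the
global fit is the standard way MM dropout curves are used for
full-transcript data. Degenerate inputs: a matrix with no zeros yields the
smallest positive float (all weights ≈ 1) with a warning instead of failing,
so dense matrices flow through the pipeline; an all-zero matrix raises.

The entrywise loss weight is `w_ij = 1 − P_ij`, forced to exactly 0 where
the observation is 0. That exactness is load-bearing: it is what makes the
log-scale reconstruction loss well defined without ever evaluating the log
of a zero, and it means an arbitrary prediction at a dropout site incurs no
reconstruction penalty — dropouts are filled in by generalization from
trusted entries, not fitted.

## Autoencoder

Architecture for G genes: `G → 2G → ⌈G/2⌉ → 2G → G`, ReLU on the three
hidden layers. The output activation is softplus rather than ReLU so the
reconstruction is strictly positive and its log1p is smooth everywhere; a
ReLU output would produce exact zeros inside the log and kill gradients.
The network is implemented directly in numpy (forward pass, backprop, Adam,
inverted dropout); at the matrix sizes this package targets the dense
matrix products involved are small, and single-threaded numpy execution
makes the bitwise-determinism contract easy to honour.

Objective (sum over entries, not mean — histories are comparable across
batch sizes because the recorded per-epoch loss is always the full-data sum):

```
Σ_ij w_ij (log1p(ŷ_ij) − log1p(y_ij))² + α Σ_layers ‖W‖²_F
```

Biases are excluded from the penalty, which covers connection weights only.
Working in log1p rather than log space is a deliberate choice: the weight of
every zero entry is exactly 0, so the only terms that ever carry loss are
nonzero entries, where log(1+y) is a smooth monotone surrogate for log(y)
that stays finite as predictions approach zero.

Training: each cell (column) is one example; mini-batches of 64 cells are
reshuffled every epoch with a seeded generator; Adam with learning rate
1e-3 (β₁ 0.9, β₂ 0.999), hidden-unit dropout rate 0.2, L2 rate α = 1e-4 by
default with k-fold cross-validation over cells available (`select_alpha`,
held-out score = weighted reconstruction sum without the penalty, ties
toward the larger α). The L2 gradient `2αW` is applied at every step.

**Early stopping.** The full-data loss under constant-rate Adam with
sum-reduction oscillates noticeably around a falling trend, so a classic
"no new best value for p epochs" rule fires long before the fit is done.
Instead the stopper compares the mean loss over the last `patience` epochs
(default 100) with the mean over the preceding `patience` epochs and stops
when the relative improvement drops below `tol` (default 1e-3), up to
`max_epochs` = 1000. On the package's desk-scale reference problem (200
genes × 300 cells at 90% sparsity) the reconstruction error plateaus within
these defaults while shorter schedules leave both the error and the
recovered cluster structure visibly unconverged. `patience=0` disables
early stopping.

Determinism: a fixed seed fixes initialization, batch order, and dropout
masks; two runs with identical inputs and config are bitwise identical
(single-threaded numpy, no atomics).

## Imputation policies

`zeros-only` (default) replaces only observed zeros with the network's
inverse-log1p prediction (clipped at 0) and passes every nonzero through
unchanged — the method's goal is to correct dropouts, and the loss already
anchors the reconstruction to nonzero entries. `denoise-all` returns the
full reconstruction, useful when the downstream analysis benefits from
smoothing observed values too. Outputs are always non-negative and keep the
input's gene/cell identifiers.

The `weighting="uniform"` option replaces the MM weights with all-ones,
turning the objective into a plain log-space MSE in which observed zeros are
targets. This is the ablation that isolates the contribution of the weighted
loss: on 90%-sparse simulations the uniform variant learns to predict zeros
at dropout sites and barely improves on the raw matrix, while the weighted
loss recovers the truth to a several-fold smaller log-scale RMSE.

## Simulator

Gamma-Poisson group-structured counts in the Splatter mould: per-gene base
means `Gamma(shape 0.6, rate 0.3)`; each gene is a marker with probability
`de_prob` (default 0.2) and markers draw an independent
`LogNormal(0.3, 0.4)` fold factor per group; cells are assigned to groups
uniformly; library sizes are `LogNormal(9.0, 0.25)` (≈ 8,100 counts
median); expected expression is the library-size-scaled, group-profile-
normalized rate; counts are Poisson (gamma-Poisson when `dispersion > 0`).
The defaults give a desk-scale dataset whose ground truth separates cleanly
under the package's own embed-then-cluster pipeline, which is the property
the evaluation depends on.

Corruption applies the model's own keep-probability `t/(km + t)` entrywise,
so simulated dropout matches the imputer's modelling assumption (a
`logistic` option exists for misspecification experiments). `km` is found by
log-scale bisection so the *expected* zero fraction hits the target
sparsity within 0.005 — calibration is deterministic given the truth
matrix, and realized sparsity concentrates within ±0.02 of the target for
matrices of ≥ 10⁵ entries. Infeasible targets (below the truth's own zero
fraction, or beyond the search interval) raise with the feasible range.

What the simulator does **not** emulate: mean-variance (BCV) trends,
trajectories/paths, batch effects, doublets, ambient RNA, or UMI-specific
zero structure. Passing tests on these simulations therefore demonstrates
correct behaviour under a correctly-specified, group-structured dropout
model — not performance on droplet data, which the MM assumption explicitly
excludes.

`mask_to_sparsity` supports the complementary real-data benchmark design:
it zeroes exactly as many uniformly chosen nonzero entries as needed to
reach a target sparsity, so a dense, low-noise dataset can serve as its own
ground truth.

## Evaluation

Partition agreement: ARI (permutation-model adjusted Rand), AMI
(arithmetic normalization, natural-log entropies; degenerate constant
labelings score 0), and FMI (pair-counting), all delegated to scikit-learn
behind the package's surface and verified in the test suite against
independent brute-force contingency/pair-counting/hypergeometric oracles.
Silhouette is computed on the 2-D embedding with the *predicted* labels — a
visualization-tightness measure, deliberately not an accuracy measure.

`cluster_and_score` pipeline: scale each cell to the median total count,
log1p, embed to 2-D (PCA implemented natively with sign-fixed components so
one path is fully deterministic; t-SNE and UMAP delegated to scikit-learn
and umap-learn), cluster with k-means (10 seeded restarts) or Ward-linkage
hierarchical clustering at the known number of groups, then score against
the true labels. The total-count normalization step is essential, not
cosmetic: with lognormal library sizes the first principal component of the
unnormalized log matrix is the library-size axis, and even ground-truth
matrices fail to separate in two components without it. k is taken as the
true number of groups when truth is known; no model selection of k is
attempted. A Leiden hook exists (kNN graph of the embedding + leidenalg) as
a data-driven alternative that does not enforce k.

RMSE between matrices is computed on log1p values over all entries by
default (`scale="raw"` available) — the same scale the loss and the
heatmap-style visual comparisons operate on.

## Problem sizes

Reference problems used throughout the tests: 200 genes × 300 cells × 4
groups at 90% sparsity for end-to-end properties (three seeds; one
imputation ≈ 30 s on one CPU core), and 800 × 1,000 for simulator
calibration checks. The same pipeline at 800 × 1,000 trains in minutes and
reproduces the qualitative picture with much stronger absolute numbers
(e.g. PCA+k-means ARI 0.17 → 0.73 raw → imputed at seed 1); the small
reference keeps the full suite fast while preserving every ordering the
package asserts. Note the information ceiling shrinks with the problem: at
200 × 300/90% even an oracle classifier with the true group profiles and
dropout law reaches only ARI ≈ 0.38, so small absolute clustering scores at
this scale reflect the problem, not the method.

## Known limitations

- The MM dropout assumption restricts valid inputs to full-transcript
  counts or TPM; the package warns on, but does not refuse, other scales.
- A single global K_M ignores gene-specific capture efficiency.
- Early stopping monitors training loss (the method is unsupervised); there
  is no validation-based stopping by default.
- The trained network is tied to the gene set it was trained on; there is no
  cross-dataset transfer.
- With `denoise-all`, entries observed at high expression are smoothed
  toward the manifold, which can shrink genuine outliers.
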