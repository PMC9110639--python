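# nisc

Autoencoder imputation for sparse single-cell RNA-seq count matrices, with a
reconstruction loss weighted by a Michaelis–Menten dropout model.

## The problem

Single-cell RNA-seq count matrices are riddled with *dropouts*: transcripts
that are present in a cell but lost during library preparation (chiefly at
the reverse-transcription step), so they appear as zeros. At 80–90% sparsity
these technical zeros blur cell-type structure badly enough that embedding
and clustering pipelines stop working. `nisc` imputes the dropouts with a
denoising autoencoder whose loss knows which entries to trust.

## The model

Reverse transcription is an enzyme reaction, so for full-transcript
protocols the probability that gene *i* in cell *j* drops out follows
Michaelis–Menten saturation in its expression level *S<sub>ij</sub>*:

```
P_ij = 1 − S_ij / (K_M + S_ij)
```

*K<sub>M</sub>* (the Michaelis constant) is the expression level at which a
transcript is lost half the time; `nisc` estimates it by least squares of
each gene's zero fraction against the MM curve at the gene's mean expression.

A three-hidden-layer autoencoder (widths 2G, ⌈G/2⌉, 2G for G genes; ReLU
hidden units, softplus output) maps each cell's log1p expression vector to a
denoised reconstruction ŷ, trained with Adam to minimize

```
Loss = Σ_ij (1 − P_ij) · (log(1+ŷ_ij) − log(1+y_ij))² + α · ‖β‖²
```

plus dropout regularization on the hidden units. The weight 1 − P<sub>ij</sub>
is exactly 0 at observed zeros, so dropouts never pull the reconstruction
toward zero — the network learns the expression manifold from the entries it
can trust and fills in the rest. ‖β‖² is the sum of squared connection
weights (biases excluded) and α the L2 rate, selectable by cross-validation.

Two output policies: `zeros-only` (default) passes observed nonzeros through
and replaces only zeros; `denoise-all` replaces every entry.

The package also ships a Splatter-style gamma-Poisson simulator (group
structure, marker-gene fold changes, lognormal library sizes, MM dropout
calibrated to a target sparsity) and an evaluation module (ARI/AMI/FMI,
silhouette, log1p RMSE, PCA/t-SNE/UMAP + k-means/hierarchical scoring).

## Worked example

```python
import nisc

sim = nisc.simulate(n_genes=200, n_cells=300, n_groups=4,
                    de_prob=0.2, target_sparsity=0.9, seed=1)
print(f"raw sparsity: {sim.raw.sparsity():.3f} (dropout km = {sim.km_used:.1f})")

imputed, trace = nisc.impute(sim.raw)
print(f"trained {trace.epochs_run} epochs, final loss {trace.loss_history[-1]:.1f}")
print(f"RMSE vs truth (log1p): raw {nisc.rmse(sim.truth, sim.raw):.3f} "
      f"-> imputed {nisc.rmse(sim.truth, imputed):.3f}")

for name, m in [("raw", sim.raw), ("imputed", imputed)]:
    rep = nisc.cluster_and_score(m, sim.labels, k=4, seed=0)
    print(f"{name}: ARI {rep.ari:.3f}  AMI {rep.ami:.3f}  FMI {rep.fmi:.3f}")
```

prints

```
raw sparsity: 0.894 (dropout km = 287.2)
trained 1000 epochs, final loss 36.6
RMSE vs truth (log1p): raw 2.866 -> imputed 0.446
raw: ARI 0.009  AMI 0.013  FMI 0.266
imputed: ARI 0.172  AMI 0.253  FMI 0.385
```

Ninety percent of the entries were zeroed by simulated dropout; imputation
cuts the log-scale reconstruction error against the known ground truth by
~6x and lifts every clustering-agreement index above the raw data's
(near-chance) level. At this deliberately small problem size the absolute
clustering numbers stay modest — most of each cell's signal is destroyed —
but the ordering imputed > raw is stable across seeds.

A scikit-learn-style estimator is available too (cells as rows):

```python
from nisc import NISCImputer
X_imputed = NISCImputer(seed=1).fit_transform(X_raw)  # X_raw: cells x genes
```

and the same pipeline from the shell:

```sh
nisc simulate --genes 200 --cells 300 --groups 4 --sparsity 0.9 --seed 1 --out-dir sim/
nisc impute --input sim/raw.csv --output imputed.csv --seed 1
nisc evaluate --imputed imputed.csv --labels sim/labels.csv --truth sim/truth.csv \
     --k 4 --out report.json
```

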