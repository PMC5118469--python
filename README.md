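# rkcca

Regularized kernel canonical correlation analysis (CCA) for two or more
timeseries datasets.

CCA addresses a recurring question in multivariate analysis — prominently
in neuroimaging, where several subjects watch the same stimulus and each
yields a timepoints × voxels response matrix: **what dimensions of
variation are shared across datasets that describe the same samples with
different features?** CCA finds, for each dataset, projection weights
whose projected timeseries (the *canonical components*) are maximally
correlated across datasets. Unlike regression it designates no dependent
dataset, the datasets may have different feature counts, and the shared
dimensions it recovers are directly interpretable. `rkcca` is aimed at
researchers who need that analysis with L2 regularization (essential when
features outnumber samples), optional kernelization, principled
hyperparameter selection, and cross-dataset prediction of held-out data.

## Model

Given column-centered datasets $X_1, \dots, X_m$ ($m \ge 2$) with a shared
sample count, canonical weights $w_i$ solve the block generalized
eigenvalue problem

```math
\begin{pmatrix} 0 & C_{12} & \cdots \\ C_{21} & 0 & \cdots \\ \vdots & & 0 \end{pmatrix}
\begin{pmatrix} w_1 \\ w_2 \\ \vdots \end{pmatrix}
= \rho
\begin{pmatrix} C_{11} + \lambda I & & \\ & C_{22} + \lambda I & \\ & & \ddots \end{pmatrix}
\begin{pmatrix} w_1 \\ w_2 \\ \vdots \end{pmatrix},
```

where $C_{ij} = X_i^\top X_j$ (raw cross-products; in kernel mode
$K_i K_j$ for Gram matrices $K_i$) and $\lambda \ge 0$ is the L2
regularization coefficient. The canonical correlations $\rho_k$ are the
correlations of matched component pairs (mean over dataset pairs for
$m > 2$). As $\lambda \to \infty$ the solution approaches partial least
squares; at $\lambda = 0$ it is classical CCA.

A fitted model predicts held-out data across datasets: each other
dataset is projected through its weights, the projections are averaged,
and the average is mapped into the target's feature space through a
spectral-cutoff pseudoinverse of the target's weight matrix. Per-feature
Pearson correlations between predicted and actual data quantify accuracy,
with an asymptotic Fisher-z test plus Benjamini–Hochberg FDR control for
significance. Hyperparameters ($\lambda$, number of components) are
chosen by grid search with Monte-Carlo cross-validation that holds out
20% of the training samples in blocks of 10 consecutive timepoints —
appropriate for autocorrelated timeseries.

## Worked example

Two synthetic datasets (4 and 5 features, 1000 samples) are built from
two shared Gaussian latent variables (weight 0.75) plus independent noise
(weight 0.25); a correct analysis should find exactly two meaningful
canonical components.

```python
import numpy as np
import rkcca

blocks, latents = rkcca.generate_example(rkcca.SyntheticSpec(seed=0))
train1, test1 = rkcca.split_halves(blocks[0])
train2, test2 = rkcca.split_halves(blocks[1])

model = rkcca.KernelCCA(n_components=4, reg=0.0, kernel="none")
model.fit([train1, train2])
print("canonical correlations:", np.round(model.cancorrs_, 3))

result = model.predict([test1.raw(), test2.raw()])
print("prediction correlations (dataset 1):", np.round(result.corrs[0], 3))
print("prediction correlations (dataset 2):", np.round(result.corrs[1], 3))

sig = rkcca.prediction_significance(np.concatenate(result.corrs),
                                    n_test=500, alpha=0.05)
print("significant dimensions:", int(sig.significant_mask.sum()), "of 9")

search = rkcca.GridSearchCCA(regs=(0.0, 1e2, 1e4, 1e6), numccs=(1, 2, 3, 4),
                             kernel="none", random_state=0)
search.fit([train1, train2])
print("best reg:", search.best_reg_, "best numCC:", search.best_numcc_)
print("refit canonical correlations:", np.round(search.cancorrs_, 3))
```

Output:

```
canonical correlations: [0.951 0.941 0.124 0.026]
prediction correlations (dataset 1): [0.924 0.912 0.91  0.905]
prediction correlations (dataset 2): [0.932 0.9   0.927 0.911 0.895]
significant dimensions: 9 of 9
best reg: 1000000.0 best numCC: 2
refit canonical correlations: [0.949 0.942]
```

The first two canonical correlations (~0.95) capture the two latent
variables; the remaining two are noise-level. All nine held-out
dimensions are predicted with correlation ~0.9 and pass the FDR-corrected
significance test, and cross-validation correctly identifies two
components as optimal, preferring a regularized fit (the latents are
drawn independently but are not exactly orthogonal in sample, which
regularization accommodates).

The same workflow is available from the shell:

```
rkcca simulate --n-samples 1000 --seed 0 --out-prefix sim
rkcca fit sim_dataset1.txt sim_dataset2.txt --ktype none --reg 0 --numcc 4 --out model.h5
rkcca cv sim_dataset1.txt sim_dataset2.txt --regs 0,100 --numccs 1,2,3,4 --out cv.h5
rkcca validate sim_dataset1.txt sim_dataset2.txt --model model.h5 --out validated.h5
rkcca significance --model validated.h5 --alpha 0.05
```

Estimators follow scikit-learn conventions (`get_params`/`set_params`,
fitted attributes with trailing underscores) and fitted models round-trip
through HDF5 archives via `rkcca.save_model` / `rkcca.load_model`.

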