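# Methods

## Model and estimation

`rkcca` estimates canonical correlation analysis (CCA) between $m \ge 2$
datasets $X_1, \dots, X_m \in \mathbb{R}^{n \times p_i}$ observed over the
same $n$ samples. All data are column-centered at ingest and the centering
offsets are retained, so held-out data can be centered with the *training*
means — predictions are honest out-of-sample (prediction correlations are
shift-invariant, so this choice affects predicted values, not accuracy).

Rather than the iterative deflation formulation, the whole solution is
obtained in one shot as a block generalized eigenvalue problem: the
left-hand side has zero diagonal blocks and cross-product blocks
$C_{ij} = X_i^\top X_j$ off the diagonal; the right-hand side is block
diagonal with $C_{ii} + \lambda I$. Eigenvectors, split row-wise into
per-dataset segments, are the canonical weights; for two datasets the
spectrum comes in $\pm$ pairs and the leading (non-negative) branch is
kept. Canonical correlations are computed empirically as Pearson
correlations of matched component columns — for more than two datasets,
the mean over all dataset pairs, which is this package's contract (the
two-dataset case reduces to the usual definition).

In dual (kernel) mode the same block problem is assembled from Gram
matrices ($K_i K_j$ off-diagonal, $K_i^2 + \lambda I$ on the diagonal) and
the dual solutions $\alpha_i$ are pulled back to feature space as
$w_i = X_i^\top \alpha_i$, so components, persistence and prediction
always operate on feature-space weights regardless of mode. For the
linear kernel this pullback is exact (primal and dual fits agree to
$10^{-6}$ in the tests); for nonlinear kernels it is the linear
feature-space representative of the dual solution, and component/
prediction outputs should be interpreted accordingly.

Assumptions worth stating: samples are exchangeable rows shared across
datasets (the CV scheme additionally assumes short-range autocorrelation,
see below); relationships sought are linear in the (possibly kernelized)
features; and datasets are dependent through common latent factors rather
than causally ordered.

## Regularization scale

Cross-products are **raw** — not divided by $n$ or $n-1$. The
regularization coefficient $\lambda$ therefore competes with sums of
squares of order $n \cdot \mathrm{var}$, not with variances. A $\lambda$
of $10^2$ against 500 samples of unit-variance data is a moderate ridge;
the same data normalized per-sample would need $\lambda \sim 0.2$. Users
porting regularization grids from covariance-scaled implementations must
rescale by $n$. As $\lambda \to \infty$ the right-hand side is dominated
by $\lambda I$ and the leading weights converge in direction to the top
singular vectors of the cross-covariance — the partial-least-squares
limit, verified in the tests at $\lambda = 10^{10}$ against a direct SVD.

## Kernels

* linear: $x_i \cdot x_j$;
* Gaussian: $\exp(-\lVert x_i - x_j\rVert^2 / (2\sigma^2))$ with
  $\sigma$ = `gausigma` (default 1.0);
* polynomial: homogeneous $(x_i \cdot x_j)^d$ with $d$ = `degree`
  (default 2), no additive offset.

Grams are symmetrized exactly by averaging with their transpose, are not
trace-normalized, and are **not** double-centered: data are
column-centered before kernel evaluation instead. For nonlinear kernels
the two centering conventions differ; column centering was chosen so that
the primal and dual pipelines share one preprocessing step, and is
documented here as a deliberate convention. Kernel CCA with an invertible
kernel and $\lambda = 0$ admits a trivial perfectly-correlated solution,
so that combination triggers a warning.

## Prediction, explained variance, significance

To predict held-out dataset $i$, every other dataset is projected through
its weights, projections are averaged (unweighted — the symmetric choice,
since the formulation designates no direction), and the average $\bar U$
is mapped back by the least-norm solution of $\hat X_i W_i = \bar U$,
i.e. $\hat X_i = \bar U W_i^{+}$. The pseudoinverse is regularized by
spectral cutoff: singular values below `cutoff` times the **largest**
singular value are zeroed (relative thresholding keeps the operation
scale-free; `cutoff = 0` is the plain Moore–Penrose inverse, with the
standard eps-scale rank tolerance).

Explained variance of component $k$ for held-out feature $f$ is the
squared Pearson correlation between the held-out component timeseries
$X_i w_{ik}$ and the feature column — identical to the $R^2$ of the best
single-regressor least-squares fit (asserted to $10^{-10}$ in the tests),
and bounded in $[0, 1]$ per (component, feature).

Prediction correlations are tested with the asymptotic Fisher-z
transform, $z = \operatorname{atanh}(r)\sqrt{n_{\mathrm{test}} - 3}$,
two-sided normal p-values, and Benjamini–Hochberg step-up FDR control
(via `statsmodels`; a hand-coded step-up is the independent oracle in the
test suite). Correlations at $\pm 1$ are clamped to $1 - 10^{-15}$ before
the transform.

## Hyperparameter selection

`GridSearchCCA` scores each (λ, numCC) candidate by Monte-Carlo block
cross-validation: per iteration, `floor(0.2·n / 10)` disjoint blocks of
10 consecutive samples (defaults) are held out, the model is fit on the
remainder, the holdout is predicted across datasets, and the score is the
mean over datasets of the mean of the top `ceil(select · p)` per-feature
prediction correlations (`select` = 0.2 by default; contiguous blocks
respect timeseries autocorrelation, and the top-fraction metric discounts
dimensions that are mostly noise). Scores are averaged over `numcv` = 10
iterations; ties are broken toward the smallest component count, then the
largest regularization (parsimony first, shrinkage second). Holdout
blocks start at multiples of the block length and are drawn without
replacement, so splits are disjoint and reproducible given (seed,
iteration); trailing remainder samples always stay in training. A grid
cell whose fit fails (e.g. an infeasible component count) scores
$-\infty$ with a warning instead of aborting the search. The winning pair
is refit on all training data.

Default grids: 10 log-spaced $\lambda$ in $[10^{-3}, 10]$ and component
counts 5–10.

## Synthetic data generator

`generate_example` draws shared standard-normal latent variables and
builds each dataset feature as `signal_weight`·latent +
`noise_weight`·independent standard normal (defaults 0.75/0.25; default
wiring: a 4-feature dataset assigned latents [1,2,1,2] and a 5-feature
dataset [1,2,1,2,1], 1000 samples). Draw order is fixed (latents first,
then per-dataset noise) so a seed fully determines the output. Latents
are independent by construction but *not* orthogonalized — their sample
correlation is the reason a small ridge typically improves the fit, and
removing it would erase the phenomenon the model-selection experiment
demonstrates. Two columns sharing a latent have population correlation
$s^2 / (s^2 + \sigma^2) = 0.9$ at the defaults; columns on different
latents are uncorrelated in population.

What the generator does **not** emulate: hemodynamic response functions,
temporally autocorrelated noise, spatial feature structure, or
heavy-tailed artifacts. Passing tests on this data demonstrate correct
recovery of linear latent structure under i.i.d. Gaussian noise; they do
not by themselves establish performance on real neuroimaging data, where
autocorrelation makes the block-CV scheme matter and where regularization
paths are far more consequential.

In the replicated experiments each repetition redraws *everything* —
latents and noise — so repetition variability reflects the full sampling
distribution of the construction.

## Numerical choices

* The symmetric-definite generalized eigenproblem is solved by
  `scipy.linalg.eigh` after both sides are explicitly symmetrized
  (averaging with transposes kills floating-point asymmetry).
* When $\lambda = 0$ a ridge of $10^{-8}$ × mean(diagonal) is added to
  the right-hand side purely for solvability, with a logged notice; the
  jitter is orders of magnitude below data scale and unregularized
  results remain reproducible (canonical correlations are computed as
  component correlations, which are invariant to weight scaling, so the
  jitter's effect is far below test tolerances).
* Eigenvector sign is fixed by forcing the largest-magnitude entry of
  each first-dataset weight segment positive; canonical weights are
  intrinsically sign-ambiguous and all tests are sign-invariant.
* Components and canonical correlations are reordered by descending
  canonical correlation (stable sort), so `cancorrs_` is non-increasing
  even under heavy regularization where the eigenvalue and correlation
  orders can differ.
* Zero-variance columns or components yield correlation 0 with a warning
  rather than NaN.
* Ties among equal grid scores and equal eigenvalues are broken by stable
  ordering; no test depends on order within ties.

## Problem sizes in the shipped experiments

The replicated studies use 50 repetitions for the fixed-hyperparameter
experiment and 200 for the cross-validated search (each repetition: a 4×4
grid × 10 CV iterations on 500 training samples) — sizes at which the
replicate means are stable to well within the tolerances asserted, while
the whole suite runs in about a minute on one CPU.

## Known limitations

* Primal mode materializes the full block matrix (sum of feature counts
  squared); beyond a few thousand total features, use kernel mode — that
  is the intended wide-data path.
* No sparse or low-rank (Nyström) kernel approximations; no precomputed-
  kernel input.
* Only the spectral-cutoff pseudoinverse is offered for prediction (no L2
  penalized inverse).
* K-fold (non-Monte-Carlo) and nested cross-validation are out of scope,
  as is distributed execution.
* `cancorrs_` for more than two datasets is the mean-over-pairs
  convention; other multi-set CCA variants define other summaries.
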