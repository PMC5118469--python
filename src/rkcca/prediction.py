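"""Cross-dataset prediction, explained variance and significance testing.

Once canonical weights are estimated, a held-out sample of one dataset can
be predicted from the other datasets: project each other dataset onto the
canonical space through its weights, average the projections, and map the
average back to the target's feature space through a (spectral-cutoff
regularized) pseudoinverse of the target's weight matrix. Prediction
accuracy is the per-feature Pearson correlation between predicted and
actual held-out columns.

Held-out data are centered with the *training* column means, never their
own, so prediction is honest out-of-sample; Pearson correlations are
shift-invariant, so this choice affects predicted values but not accuracy.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from ._block import as_raw

__all__ = [
    "PredictionResult", "EVResult", "SignificanceResult",
    "regularized_pinv", "predict_heldout", "explained_variance",
    "prediction_significance",
]


@dataclass(frozen=True)
class PredictionResult:
    """Cross-dataset predictions and per-feature accuracy correlations."""

    preds: List[np.ndarray]   # per dataset, n_test x n_features
    corrs: List[np.ndarray]   # per dataset, length n_features


@dataclass(frozen=True)
class EVResult:
    """Per-component, per-feature explained-variance fractions (R^2)."""

    ev: List[np.ndarray]      # per dataset, n_components x n_features


@dataclass(frozen=True)
class SignificanceResult:
    """Fisher-z p-values and the Benjamini-Hochberg decision."""

    p_values: np.ndarray
    q_threshold: float
    significant_mask: np.ndarray


def regularized_pinv(W, cutoff: float = 0.0) -> np.ndarray:
    """Moore-Penrose pseudoinverse with spectral-cutoff regularization.

    Singular values smaller than ``cutoff`` times the largest singular
    value are zeroed before reconstruction; ``cutoff=0`` gives the plain
    pseudoinverse. The threshold is relative to the largest singular value
    so the operation is scale-free.
    """
    if not 0.0 <= cutoff < 1.0:
        raise ValueError(f"cutoff must lie in [0, 1), got {cutoff}")
    w = np.atleast_2d(np.asarray(W, dtype=np.float64))
    if not w.any():
        warnings.warn("pseudoinverse of an all-zero matrix is zero")
        return np.zeros(w.T.shape)
    u, s, vt = np.linalg.svd(w, full_matrices=False)
    # fall back to the usual eps-scale rank tolerance when cutoff == 0
    tol = max(cutoff, np.finfo(np.float64).eps * max(w.shape)) * s[0]
    inv = np.where(s >= tol, 1.0 / np.where(s > 0, s, 1.0), 0.0)
    inv[s == 0] = 0.0
    return (vt.T * inv) @ u.T


def _safe_corr(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation, with zero-variance columns scored as 0."""
    sx, sy = x.std(), y.std()
    if sx == 0 or sy == 0:
        warnings.warn("zero-variance column; correlation recorded as 0")
        return 0.0
    xc, yc = x - x.mean(), y - y.mean()
    return float(xc @ yc / (np.linalg.norm(xc) * np.linalg.norm(yc)))


def _centered_test_blocks(model, test_blocks) -> List[np.ndarray]:
    if len(test_blocks) != model.n_datasets_:
        raise ValueError(f"got {len(test_blocks)} test datasets but the "
                         f"model was trained on {model.n_datasets_}")
    out = []
    for i, (tb, mu, w) in enumerate(zip(test_blocks, model.means_,
                                        model.weights_)):
        x = as_raw(tb)
        if x.shape[1] != w.shape[0]:
            raise ValueError(f"test dataset {i} has {x.shape[1]} features "
                             f"but the model expects {w.shape[0]}")
        out.append(x - mu)
    return out


def predict_heldout(model, test_blocks: Sequence, cutoff=None
                    ) -> PredictionResult:
    """Predict each held-out dataset from all the others.

    Parameters
    ----------
    model : fitted KernelCCA
        Supplies the canonical weights and the training column means.
    test_blocks : sequence of array-like or DataBlock
        Held-out data, in the same order as at training time.
    cutoff : float, optional
        Spectral-cutoff threshold for the weight pseudoinverse; defaults
        to the model's ``cutoff`` parameter.
    """
    if len(test_blocks) < 2:
        raise ValueError("cross-dataset prediction needs >= 2 datasets")
    if cutoff is None:
        cutoff = getattr(model, "cutoff", 0.0)
    xs = _centered_test_blocks(model, test_blocks)
    projections = [x @ w for x, w in zip(xs, model.weights_)]
    preds, corrs = [], []
    for i, w in enumerate(model.weights_):
        ubar = np.mean([projections[j] for j in range(len(xs)) if j != i],
                       axis=0)
        pred = ubar @ regularized_pinv(w, cutoff)
        preds.append(pred)
        corrs.append(np.array([_safe_corr(pred[:, f], xs[i][:, f])
                               for f in range(pred.shape[1])]))
    return PredictionResult(preds, corrs)


def explained_variance(model, test_blocks: Sequence) -> EVResult:
    """Variance of each held-out feature explained by each component.

    For dataset ``i`` and component ``k``, the held-out component
    timeseries is the centered test data projected onto weight column
    ``k``; the entry ``ev[k, f]`` is the squared Pearson correlation of
    that timeseries with held-out feature ``f`` — the R^2 of the best
    single-regressor fit.
    """
    xs = _centered_test_blocks(model, test_blocks)
    out = []
    for x, w in zip(xs, model.weights_):
        u = x @ w
        ev = np.empty((u.shape[1], x.shape[1]))
        for k in range(u.shape[1]):
            if u[:, k].std() == 0:
                warnings.warn(f"zero-variance component {k}; its explained "
                              "variance is recorded as 0")
                ev[k] = 0.0
                continue
            for f in range(x.shape[1]):
                ev[k, f] = _safe_corr(u[:, k], x[:, f]) ** 2
        out.append(ev)
    return EVResult(out)


def prediction_significance(corrs, n_test: int, alpha: float = 0.05
                            ) -> SignificanceResult:
    """Asymptotic (Fisher z) test of prediction correlations with FDR control.

    Each correlation ``r`` is mapped to ``z = atanh(r) * sqrt(n_test - 3)``
    and a two-sided normal p-value; the family is then thresholded with the
    Benjamini-Hochberg step-up procedure at level ``alpha``.
    ``q_threshold`` is the largest p-value still declared significant
    (0.0 when nothing passes).
    """
    if n_test < 4:
        raise ValueError(f"n_test must be >= 4, got {n_test}")
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    r = np.asarray(corrs, dtype=np.float64).ravel()
    r = np.clip(r, -1.0 + 1e-15, 1.0 - 1e-15)
    z = np.arctanh(r) * np.sqrt(n_test - 3)
    p = 2.0 * norm.sf(np.abs(z))
    reject, _, _, _ = multipletests(p, alpha=alpha, method="fdr_bh")
    q_threshold = float(p[reject].max()) if reject.any() else 0.0
    return SignificanceResult(p, q_threshold, reject)
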