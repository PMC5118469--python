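"""Multi-set CCA as a regularized block generalized eigenvalue problem.

Given ``m >= 2`` column-centered datasets :math:`X_1 \\dots X_m` sharing a
sample count, canonical weights are the leading eigenvectors of

.. math::

    \\begin{pmatrix} 0 & C_{12} & \\cdots \\\\ C_{21} & 0 & \\cdots \\\\
    \\vdots & & 0 \\end{pmatrix} w
    = \\rho \\,
    \\begin{pmatrix} C_{11} + \\lambda I & & \\\\ & C_{22} + \\lambda I & \\\\
    & & \\ddots \\end{pmatrix} w,

where :math:`C_{ij} = X_i^T X_j` in primal (covariance) mode or
:math:`K_i K_j` in dual (kernel) mode. Cross-products are raw — not
divided by the sample count — so the regularization coefficient
:math:`\\lambda` is on the scale of raw sums of squares; this matters when
choosing regularization grids. As :math:`\\lambda \\to \\infty` the leading
weights converge in direction to the singular vectors of the
cross-covariance (the partial-least-squares limit).

The symmetric-definite problem is solved by whitening against the
right-hand side (``scipy.linalg.eigh``); both sides are explicitly
symmetrized first, and when :math:`\\lambda = 0` a tiny ridge
(``1e-8`` times the mean diagonal) makes the right-hand side positive
definite without measurably moving the solution.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import scipy.linalg
from sklearn.base import BaseEstimator

from ._block import DataBlock, as_block
from .exceptions import SingularityError
from .kernels import GramMatrix, KernelSpec, make_gram
from . import prediction as _prediction

__all__ = ["EigenSystem", "build_eigensystem", "solve_eigensystem",
           "canonical_correlations", "KernelCCA", "fit_cca"]

logger = logging.getLogger(__name__)

#: relative ridge added to the rhs when reg == 0, purely for solvability
_ZERO_REG_JITTER = 1e-8


@dataclass(frozen=True)
class EigenSystem:
    """The block eigenproblem: zero-diagonal lhs, regularized rhs."""

    lhs: np.ndarray
    rhs: np.ndarray
    block_dims: Tuple[int, ...]
    reg: float


def _block_matrices(blocks) -> List[np.ndarray]:
    mats = []
    for b in blocks:
        if isinstance(b, GramMatrix):
            mats.append(b.values)
        elif isinstance(b, DataBlock):
            mats.append(b.values)
        else:
            mats.append(as_block(b).values)
    return mats


def build_eigensystem(blocks: Sequence, reg: float) -> EigenSystem:
    """Assemble the block generalized eigenvalue problem.

    ``blocks`` may be DataBlocks/arrays (primal mode: cross-product blocks
    :math:`X_i^T X_j`) or GramMatrix objects (dual mode: :math:`K_i K_j`).
    The diagonal rhs blocks get ``reg`` added to their diagonal. Both
    sides are symmetrized by averaging with their transposes.
    """
    if len(blocks) < 2:
        raise ValueError(f"need >= 2 datasets, got {len(blocks)}")
    if reg < 0:
        raise ValueError(f"reg must be >= 0, got {reg}")
    mats = _block_matrices(blocks)
    n = mats[0].shape[0]
    for i, m in enumerate(mats):
        if m.shape[0] != n:
            raise ValueError(f"dataset 0 has {n} samples but dataset {i} "
                             f"has {m.shape[0]}")
    dims = tuple(m.shape[1] for m in mats)
    total = sum(dims)
    offsets = np.concatenate([[0], np.cumsum(dims)])
    lhs = np.zeros((total, total))
    rhs = np.zeros((total, total))
    for i, mi in enumerate(mats):
        si = slice(offsets[i], offsets[i + 1])
        rhs[si, si] = mi.T @ mi + reg * np.eye(dims[i])
        for j, mj in enumerate(mats):
            if j == i:
                continue
            sj = slice(offsets[j], offsets[j + 1])
            lhs[si, sj] = mi.T @ mj
    lhs = (lhs + lhs.T) / 2.0
    rhs = (rhs + rhs.T) / 2.0
    return EigenSystem(lhs, rhs, dims, float(reg))


def solve_eigensystem(es: EigenSystem, n_components: int
                      ) -> Tuple[List[np.ndarray], np.ndarray]:
    """Solve for the top eigenvectors and split them into per-block weights.

    Eigenpairs are sorted by descending eigenvalue and the leading
    ``n_components`` kept (for two blocks the spectrum comes in +/- pairs;
    the leading ones are the non-negative branch). The sign of each
    eigenvector is fixed by forcing the largest-magnitude entry of its
    first-block segment to be positive.
    """
    total = es.lhs.shape[0]
    if not 1 <= n_components <= total:
        raise ValueError(f"n_components must lie in [1, {total}], "
                         f"got {n_components}")
    rhs = es.rhs
    if es.reg == 0:
        jitter = _ZERO_REG_JITTER * float(np.mean(np.diag(rhs)))
        if jitter <= 0:
            jitter = _ZERO_REG_JITTER
        rhs = rhs + jitter * np.eye(total)
        logger.info("reg == 0: added ridge %.3e to the rhs diagonal for "
                    "numerical solvability", jitter)
    try:
        evals, evecs = scipy.linalg.eigh(es.lhs, rhs)
    except (np.linalg.LinAlgError, scipy.linalg.LinAlgError) as exc:
        raise SingularityError(
            "the regularized autocovariance is numerically singular; "
            "set reg > 0 to make the problem well posed") from exc
    vals = evals[::-1][:n_components].copy()
    vecs = evecs[:, ::-1][:, :n_components].copy()
    offsets = np.concatenate([[0], np.cumsum(es.block_dims)])
    ws = [vecs[offsets[i]:offsets[i + 1]] for i in range(len(es.block_dims))]
    # sign convention: largest-|.| entry of the first block's segment > 0
    for k in range(n_components):
        lead = ws[0][np.argmax(np.abs(ws[0][:, k])), k]
        if lead < 0:
            for w in ws:
                w[:, k] *= -1.0
    return ws, vals


def canonical_correlations(components: Sequence[np.ndarray]) -> np.ndarray:
    """Mean pairwise Pearson correlation of matched component columns.

    For two datasets this is the plain correlation between paired
    canonical components; for more, the mean over all dataset pairs.
    """
    shapes = {c.shape for c in components}
    if len(shapes) != 1:
        raise ValueError(f"component matrices differ in shape: {shapes}")
    m = len(components)
    if m < 2:
        raise ValueError("need components from >= 2 datasets")
    n_comp = components[0].shape[1]
    out = np.empty(n_comp)
    for k in range(n_comp):
        rs = [_prediction._safe_corr(components[i][:, k], components[j][:, k])
              for i in range(m) for j in range(i + 1, m)]
        out[k] = np.mean(rs)
    return out


def _resolve_kernel(kernel, gausigma=1.0, degree=2) -> Optional[KernelSpec]:
    if kernel is None or kernel == "none":
        return None
    if isinstance(kernel, KernelSpec):
        return None if kernel.ktype == "none" else kernel
    return KernelSpec(ktype=kernel, gausigma=gausigma, degree=degree)


class KernelCCA(BaseEstimator):
    """Regularized (kernel) canonical correlation analysis.

    Finds, for each of two or more datasets observed over the same
    samples, projection weights whose projected timeseries (the canonical
    components) are maximally correlated across datasets.

    Parameters
    ----------
    n_components : int, default 10
        Number of canonical components to keep.
    reg : float, default 0.0
        L2 regularization added to the diagonal of the autocovariance (or
        squared Gram) blocks. Acts on the scale of *raw* cross-products.
    kernel : {'none', 'linear', 'gaussian', 'poly'} or KernelSpec, default 'linear'
        'none' solves the primal (covariance) problem in feature space;
        the others solve the dual problem on Gram matrices, the standard
        route when features outnumber samples.
    gausigma : float, default 1.0
        Gaussian kernel width (ignored for other kernels).
    degree : int, default 2
        Polynomial kernel degree (ignored for other kernels).
    cutoff : float, default 0.0
        Spectral-cutoff threshold used when predicting held-out data.

    Attributes
    ----------
    weights_ : list of ndarray (n_features_i, n_components)
        Canonical weights per dataset, always in feature space (dual
        solutions are pulled back via ``w = X^T alpha``).
    components_ : list of ndarray (n_samples, n_components)
        Training canonical components, ``X_i w_i``.
    cancorrs_ : ndarray (n_components,)
        Canonical correlations, sorted non-increasing.
    means_ : list of ndarray (n_features_i,)
        Training column means, reused to center held-out data.
    eigenvalues_ : ndarray (n_components,)
        Generalized eigenvalues of the retained components (diagnostic).
    """

    def __init__(self, n_components: int = 10, reg: float = 0.0,
                 kernel: Union[str, KernelSpec, None] = "linear",
                 gausigma: float = 1.0, degree: int = 2,
                 cutoff: float = 0.0):
        self.n_components = n_components
        self.reg = reg
        self.kernel = kernel
        self.gausigma = gausigma
        self.degree = degree
        self.cutoff = cutoff

    def fit(self, Xs: Sequence, y=None) -> "KernelCCA":
        """Estimate the canonical mapping between the datasets in ``Xs``."""
        blocks = [as_block(x, name=f"dataset {i}")
                  for i, x in enumerate(Xs)]
        if len(blocks) < 2:
            raise ValueError(f"need >= 2 datasets, got {len(blocks)}")
        n = blocks[0].n_samples
        for i, b in enumerate(blocks):
            if b.n_samples != n:
                raise ValueError(f"dataset 0 has {n} samples but dataset "
                                 f"{i} has {b.n_samples}")
        if n < 2:
            raise ValueError("need >= 2 samples to fit")
        spec = _resolve_kernel(self.kernel, self.gausigma, self.degree)
        if spec is None:
            dmin = min(b.n_features for b in blocks)
            if self.n_components > dmin:
                raise ValueError(
                    f"n_components={self.n_components} exceeds the smallest "
                    f"feature count {dmin}; at most min over datasets of "
                    "n_features components exist in primal mode")
            es = build_eigensystem(blocks, self.reg)
            ws, evals = solve_eigensystem(es, self.n_components)
        else:
            if self.reg == 0:
                warnings.warn(
                    "kernel CCA with reg=0 admits a trivial perfectly "
                    "correlated solution for invertible kernels; set "
                    "reg > 0", UserWarning)
            grams = [make_gram(b, spec) for b in blocks]
            es = build_eigensystem(grams, self.reg)
            alphas, evals = solve_eigensystem(es, self.n_components)
            # pull dual weights back to feature space: w = X^T alpha
            ws = [b.values.T @ a for b, a in zip(blocks, alphas)]
        comps = [b.values @ w for b, w in zip(blocks, ws)]
        cancorrs = canonical_correlations(comps)
        order = np.argsort(-cancorrs, kind="stable")
        self.weights_ = [w[:, order] for w in ws]
        self.components_ = [c[:, order] for c in comps]
        self.cancorrs_ = cancorrs[order]
        self.eigenvalues_ = evals[order]
        self.means_ = [b.column_means for b in blocks]
        self.n_datasets_ = len(blocks)
        self.n_samples_ = n
        return self

    def transform(self, Xs: Sequence) -> List[np.ndarray]:
        """Project new data onto the canonical space (per dataset)."""
        xs = _prediction._centered_test_blocks(self, Xs)
        return [x @ w for x, w in zip(xs, self.weights_)]

    def predict(self, Xs: Sequence, cutoff: Optional[float] = None
                ) -> "_prediction.PredictionResult":
        """Cross-dataset prediction of each dataset in ``Xs`` from the rest."""
        return _prediction.predict_heldout(self, Xs, cutoff=cutoff)

    def compute_ev(self, Xs: Sequence) -> "_prediction.EVResult":
        """Explained variance of each held-out feature per component."""
        return _prediction.explained_variance(self, Xs)

    def score(self, Xs: Sequence, y=None) -> float:
        """Mean held-out cross-dataset prediction correlation."""
        res = self.predict(Xs)
        return float(np.mean(np.concatenate(res.corrs)))


def fit_cca(blocks: Sequence, reg: float = 0.0, n_components: int = 10,
            kernel: Union[str, KernelSpec, None] = None,
            gausigma: float = 1.0, degree: int = 2,
            cutoff: float = 0.0) -> KernelCCA:
    """Functional front end: fit and return a :class:`KernelCCA`."""
    spec = _resolve_kernel(kernel, gausigma, degree)
    est = KernelCCA(n_components=n_components, reg=reg,
                    kernel="none" if spec is None else spec,
                    gausigma=gausigma, degree=degree, cutoff=cutoff)
    return est.fit(blocks)
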