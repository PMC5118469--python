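"""Hyperparameter selection by Monte-Carlo block cross-validation.

A grid of (regularization, component-count) candidates is scored by
repeatedly holding out a fraction of the training samples in contiguous
blocks (appropriate for autocorrelated timeseries), fitting on the rest,
predicting the holdout across datasets, and averaging a top-fraction
prediction-accuracy metric over iterations. The best pair is refit on all
the data.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from sklearn.base import BaseEstimator

from ._block import as_raw
from .exceptions import SingularityError
from .kernels import KernelSpec
from .prediction import predict_heldout
from .solver import KernelCCA, _resolve_kernel

__all__ = ["CVConfig", "CVResult", "make_cv_split", "select_metric",
           "grid_search", "GridSearchCCA"]

DEFAULT_REGS = tuple(np.logspace(-3, 1, 10))
DEFAULT_NUMCCS = tuple(range(5, 11))


@dataclass(frozen=True)
class CVConfig:
    """Grid and sampling scheme for Monte-Carlo block cross-validation.

    Defaults: 10 log-spaced regularization candidates in [1e-3, 10],
    component counts 5..10, 10 Monte-Carlo iterations, 20% holdout drawn
    as disjoint blocks of 10 consecutive samples, and a top-0.2 accuracy
    metric.
    """

    regs: Tuple[float, ...] = DEFAULT_REGS
    numccs: Tuple[int, ...] = DEFAULT_NUMCCS
    numcv: int = 10
    select: float = 0.2
    holdout_fraction: float = 0.2
    block_length: int = 10
    cutoff: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.regs) == 0 or len(self.numccs) == 0:
            raise ValueError("regs and numccs must be non-empty")
        if any(r < 0 for r in self.regs):
            raise ValueError("all regularization candidates must be >= 0")
        if any(int(c) != c or c < 1 for c in self.numccs):
            raise ValueError("all component counts must be integers >= 1")
        if not 0.0 < self.select <= 1.0:
            raise ValueError(f"select must lie in (0, 1], got {self.select}")
        if not 0.0 < self.holdout_fraction < 1.0:
            raise ValueError("holdout_fraction must lie in (0, 1), "
                             f"got {self.holdout_fraction}")
        if self.block_length < 1:
            raise ValueError(f"block_length must be >= 1, "
                             f"got {self.block_length}")
        if self.numcv < 1:
            raise ValueError(f"numcv must be >= 1, got {self.numcv}")


def make_cv_split(n_samples: int, cfg: CVConfig, iteration: int
                  ) -> Tuple[np.ndarray, np.ndarray]:
    """Draw one Monte-Carlo train/holdout partition of ``range(n_samples)``.

    ``floor(holdout_fraction * n_samples / block_length)`` disjoint blocks
    of ``block_length`` consecutive samples are held out; block starts are
    aligned to multiples of ``block_length`` and drawn without
    replacement. Deterministic given ``(cfg.seed, iteration)``. Trailing
    remainder samples (an incomplete final block) always stay in training.
    """
    n_chunks = int(cfg.holdout_fraction * n_samples) // cfg.block_length
    if n_chunks < 1:
        raise ValueError(
            f"holdout_fraction*n_samples = "
            f"{cfg.holdout_fraction * n_samples:.1f} is smaller than one "
            f"block of {cfg.block_length}; use a smaller block_length")
    n_starts = n_samples // cfg.block_length
    rng = np.random.default_rng([int(cfg.seed), int(iteration)])
    starts = rng.choice(n_starts, size=n_chunks, replace=False)
    starts = np.sort(starts) * cfg.block_length
    holdout = np.concatenate([np.arange(s, s + cfg.block_length)
                              for s in starts])
    mask = np.ones(n_samples, dtype=bool)
    mask[holdout] = False
    return np.flatnonzero(mask), holdout


def select_metric(corrs_per_dataset: Sequence[np.ndarray],
                  select: float) -> float:
    """Mean prediction correlation over the best-predicted dimensions.

    Per dataset, the top ``ceil(select * p)`` of the ``p`` per-feature
    correlations are averaged; the result is the mean across datasets.
    Down-weighting poorly predicted dimensions makes the metric robust
    when many dimensions are noise.
    """
    if not 0.0 < select <= 1.0:
        raise ValueError(f"select must lie in (0, 1], got {select}")
    vals = []
    for c in corrs_per_dataset:
        c = np.asarray(c, dtype=np.float64).ravel()
        if c.size == 0:
            raise ValueError("empty correlation vector")
        k = math.ceil(select * c.size)
        vals.append(float(np.sort(c)[::-1][:k].mean()))
    return float(np.mean(vals))


@dataclass(frozen=True)
class CVResult:
    """Score grid over the (reg, numCC) candidates and the selected pair."""

    score_grid: np.ndarray            # |regs| x |numccs|, mean over iterations
    best_reg: float
    best_numcc: int
    iteration_scores: np.ndarray      # numcv x |regs| x |numccs|
    regs: Tuple[float, ...]
    numccs: Tuple[int, ...]


def grid_search(blocks: Sequence, cfg: CVConfig,
                kernel: Union[str, KernelSpec, None] = None
                ) -> Tuple[CVResult, KernelCCA]:
    """Score every (reg, numCC) pair by Monte-Carlo block CV and refit.

    A fit that fails for one grid cell records ``-inf`` for that cell
    (with a warning) instead of aborting the search. Ties on the mean
    score are broken toward the smallest component count, then the
    largest regularization.
    """
    raws = [as_raw(b) for b in blocks]
    n = raws[0].shape[0]
    spec = _resolve_kernel(kernel)
    kern = "none" if spec is None else spec
    scores = np.full((cfg.numcv, len(cfg.regs), len(cfg.numccs)), -np.inf)
    for it in range(cfg.numcv):
        train_idx, hold_idx = make_cv_split(n, cfg, it)
        train = [r[train_idx] for r in raws]
        hold = [r[hold_idx] for r in raws]
        for ri, reg in enumerate(cfg.regs):
            for ci, ncc in enumerate(cfg.numccs):
                try:
                    model = KernelCCA(n_components=int(ncc), reg=float(reg),
                                      kernel=kern, cutoff=cfg.cutoff
                                      ).fit(train)
                    res = predict_heldout(model, hold, cutoff=cfg.cutoff)
                    scores[it, ri, ci] = select_metric(res.corrs, cfg.select)
                except (ValueError, SingularityError) as exc:
                    warnings.warn(f"grid cell (reg={reg}, numCC={ncc}) "
                                  f"failed in iteration {it}: {exc}")
    grid = scores.mean(axis=0)
    # argmax with parsimony-first tie-breaking: smallest numCC, largest reg
    best_key, best = None, None
    for ri, reg in enumerate(cfg.regs):
        for ci, ncc in enumerate(cfg.numccs):
            key = (grid[ri, ci], -int(ncc), float(reg))
            if best_key is None or key > best_key:
                best_key, best = key, (float(reg), int(ncc))
    best_reg, best_numcc = best
    final = KernelCCA(n_components=best_numcc, reg=best_reg, kernel=kern,
                      cutoff=cfg.cutoff).fit(raws)
    return CVResult(grid, best_reg, best_numcc, scores,
                    tuple(cfg.regs), tuple(cfg.numccs)), final


class GridSearchCCA(BaseEstimator):
    """CCA with hyperparameters chosen by Monte-Carlo block cross-validation.

    Runs :func:`grid_search` over ``regs`` x ``numccs`` at fit time and
    exposes the refit model's attributes (``weights_``, ``components_``,
    ``cancorrs_``) alongside ``best_reg_``, ``best_numcc_`` and
    ``score_grid_``.
    """

    def __init__(self, regs: Optional[Sequence[float]] = None,
                 numccs: Optional[Sequence[int]] = None,
                 numcv: int = 10, select: float = 0.2,
                 holdout_fraction: float = 0.2, block_length: int = 10,
                 cutoff: float = 0.0,
                 kernel: Union[str, KernelSpec, None] = "linear",
                 gausigma: float = 1.0, degree: int = 2,
                 random_state: int = 0):
        self.regs = regs
        self.numccs = numccs
        self.numcv = numcv
        self.select = select
        self.holdout_fraction = holdout_fraction
        self.block_length = block_length
        self.cutoff = cutoff
        self.kernel = kernel
        self.gausigma = gausigma
        self.degree = degree
        self.random_state = random_state

    def _config(self) -> CVConfig:
        regs = DEFAULT_REGS if self.regs is None else tuple(
            float(r) for r in self.regs)
        numccs = DEFAULT_NUMCCS if self.numccs is None else tuple(
            int(c) for c in self.numccs)
        return CVConfig(regs=regs, numccs=numccs, numcv=self.numcv,
                        select=self.select,
                        holdout_fraction=self.holdout_fraction,
                        block_length=self.block_length, cutoff=self.cutoff,
                        seed=self.random_state)

    def fit(self, Xs: Sequence, y=None) -> "GridSearchCCA":
        spec = _resolve_kernel(self.kernel, self.gausigma, self.degree)
        cv, model = grid_search(Xs, self._config(),
                                kernel="none" if spec is None else spec)
        self.cv_result_ = cv
        self.best_reg_ = cv.best_reg
        self.best_numcc_ = cv.best_numcc
        self.score_grid_ = cv.score_grid
        self.best_model_ = model
        # mirror the refit model's interface
        self.weights_ = model.weights_
        self.components_ = model.components_
        self.cancorrs_ = model.cancorrs_
        self.eigenvalues_ = model.eigenvalues_
        self.means_ = model.means_
        self.n_datasets_ = model.n_datasets_
        self.n_samples_ = model.n_samples_
        return self

    def transform(self, Xs: Sequence):
        return self.best_model_.transform(Xs)

    def predict(self, Xs: Sequence, cutoff: Optional[float] = None):
        return self.best_model_.predict(Xs, cutoff=cutoff)

    def compute_ev(self, Xs: Sequence):
        return self.best_model_.compute_ev(Xs)

    def score(self, Xs: Sequence, y=None) -> float:
        return self.best_model_.score(Xs)
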