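"""Gram-matrix construction for the dual (kernelized) CCA solver.

Conventions (these are part of the package contract):

* Gaussian kernel: ``exp(-||x_i - x_j||^2 / (2 * gausigma**2))``.
* Polynomial kernel: homogeneous, ``(x_i . x_j)**degree``, no offset.
* Grams are built from column-centered data but are *not* double-centered
  and *not* normalized by the sample count — regularization coefficients
  act against raw cross-products throughout the package.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy.spatial.distance import pdist, squareform

from ._block import as_block

__all__ = ["KernelSpec", "GramMatrix", "make_gram", "KTYPES"]

KTYPES = ("linear", "gaussian", "poly")


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and its parameters.

    ``ktype`` is one of ``linear``, ``gaussian`` or ``poly``; ``gausigma``
    (default 1.0) is the Gaussian width and ``degree`` (default 2) the
    polynomial degree. The sentinel ``none`` means primal (covariance)
    mode and is rejected by :func:`make_gram`.
    """

    ktype: str = "linear"
    gausigma: float = 1.0
    degree: int = 2

    def __post_init__(self):
        if self.ktype not in KTYPES + ("none",):
            raise ValueError(f"unknown ktype {self.ktype!r}; "
                             f"expected one of {KTYPES + ('none',)}")
        if not self.gausigma > 0:
            raise ValueError(f"gausigma must be > 0, got {self.gausigma}")
        if int(self.degree) != self.degree or self.degree < 1:
            raise ValueError(f"degree must be an integer >= 1, "
                             f"got {self.degree}")


@dataclass(frozen=True)
class GramMatrix:
    """An n x n symmetric matrix of kernel evaluations of one block."""

    values: np.ndarray
    source_shape: Tuple[int, int]


def make_gram(block, spec: KernelSpec) -> GramMatrix:
    """Evaluate the kernel of ``spec`` on all row pairs of ``block``.

    The result is exactly symmetrized by averaging with its transpose.
    """
    b = as_block(block)
    m = b.values
    if not np.all(np.isfinite(m)):
        bad = int(np.flatnonzero(~np.isfinite(m).all(axis=1))[0])
        raise ValueError(f"non-finite entries in row {bad} of the data block")
    if spec.ktype == "none":
        raise ValueError("ktype 'none' means primal mode; no Gram matrix "
                         "is defined")
    if spec.ktype == "linear":
        g = m @ m.T
    elif spec.ktype == "gaussian":
        d2 = squareform(pdist(m, "sqeuclidean"))
        g = np.exp(-d2 / (2.0 * spec.gausigma ** 2))
    else:  # poly
        g = (m @ m.T) ** spec.degree
    g = (g + g.T) / 2.0
    return GramMatrix(g, m.shape)
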