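"""Column-centered data container shared across the package."""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class DataBlock:
    """One dataset as a column-centered samples x features matrix.

    Attributes
    ----------
    values : ndarray of shape (n_samples, n_features)
        The centered data (each column has mean zero).
    column_means : ndarray of shape (n_features,)
        The per-feature offsets removed at ingest; ``values + column_means``
        restores the original matrix.
    """

    values: np.ndarray
    column_means: np.ndarray

    @classmethod
    def from_array(cls, arr, name: str = "data") -> "DataBlock":
        """Validate, coerce to float64 and column-center a 2-D array."""
        a = np.asarray(arr, dtype=np.float64)
        if a.ndim == 1:
            a = a[:, None]
        if a.ndim != 2:
            raise ValueError(f"{name} must be a 2-D samples x features matrix, "
                             f"got ndim={a.ndim}")
        if a.shape[0] < 1 or a.shape[1] < 1:
            raise ValueError(f"{name} is empty (shape {a.shape})")
        if not np.all(np.isfinite(a)):
            bad = int(np.flatnonzero(~np.isfinite(a).all(axis=1))[0])
            raise ValueError(f"{name} has non-finite entries in row {bad}")
        mu = a.mean(axis=0)
        return cls(a - mu, mu)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def raw(self) -> np.ndarray:
        """Return the uncentered matrix."""
        return self.values + self.column_means


def as_block(x, name: str = "data") -> DataBlock:
    """Coerce an array-like or DataBlock to a DataBlock."""
    if isinstance(x, DataBlock):
        return x
    return DataBlock.from_array(x, name=name)


def as_raw(x) -> np.ndarray:
    """Return the uncentered float64 matrix behind an array-like or DataBlock."""
    if isinstance(x, DataBlock):
        return x.raw()
    a = np.asarray(x, dtype=np.float64)
    if a.ndim == 1:
        a = a[:, None]
    return a
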