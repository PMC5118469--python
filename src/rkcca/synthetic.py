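"""Synthetic latent-variable datasets for exercising multi-set CCA.

Each generated dataset is a weighted sum of shared Gaussian latent
variables and independent Gaussian noise: column ``f`` of dataset ``i``
equals ``signal_weight * L[assignment_i[f]] + noise_weight * eps``.
The default configuration builds two datasets (4 and 5 features) driven
by two shared latents, so a CCA between them should recover exactly two
meaningful canonical components.

The latents are drawn independently but are *not* orthogonalized: their
nonzero sample correlation is a deliberate feature of the construction
(it is what makes regularization pay off during model selection).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

from ._block import DataBlock

__all__ = ["SyntheticSpec", "generate_example", "split_halves"]

#: default feature-to-latent wiring: dataset 1 -> [L1, L2, L1, L2],
#: dataset 2 -> [L1, L2, L1, L2, L1]
DEFAULT_ASSIGNMENT: Tuple[Tuple[int, ...], ...] = ((0, 1, 0, 1), (0, 1, 0, 1, 0))


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the latent-variable generator.

    Parameters
    ----------
    n_samples : int
        Number of rows (timepoints) drawn.
    noise_weight : float
        Weight of the independent standard-normal noise added to each
        feature (default 0.25).
    signal_weight : float
        Weight of the shared latent variable in each feature (default 0.75).
    latent_assignment : tuple of tuples of int
        One tuple per dataset, mapping each feature index to a latent index.
    seed : int
        Seed for the pseudorandom stream. Draw order is fixed: the latent
        matrix first, then each dataset's noise in order, so a given
        (spec, seed) reproduces the data bit-for-bit.
    """

    n_samples: int = 1000
    noise_weight: float = 0.25
    signal_weight: float = 0.75
    latent_assignment: Tuple[Tuple[int, ...], ...] = DEFAULT_ASSIGNMENT
    seed: int = 0

    def __post_init__(self):
        if int(self.n_samples) != self.n_samples or self.n_samples <= 0:
            raise ValueError(f"n_samples must be a positive integer, "
                             f"got {self.n_samples}")
        if self.noise_weight < 0 or self.signal_weight < 0:
            raise ValueError("noise_weight and signal_weight must be >= 0")
        if self.noise_weight == 0 and self.signal_weight == 0:
            raise ValueError("noise_weight and signal_weight cannot both be 0")
        if len(self.latent_assignment) < 1:
            raise ValueError("latent_assignment must describe >= 1 dataset")
        for assign in self.latent_assignment:
            if len(assign) == 0:
                raise ValueError("each dataset needs >= 1 feature")
            for idx in assign:
                if int(idx) != idx or idx < 0:
                    raise ValueError(f"latent index {idx!r} is not a "
                                     "non-negative integer")

    @property
    def n_latents(self) -> int:
        return 1 + max(max(a) for a in self.latent_assignment)


def generate_example(spec: SyntheticSpec = SyntheticSpec()
                     ) -> Tuple[List[DataBlock], np.ndarray]:
    """Draw the interdependent datasets described by ``spec``.

    Returns
    -------
    blocks : list of DataBlock
        One column-centered block per dataset; ``block.raw()`` recovers the
        uncentered mixture exactly.
    latents : ndarray of shape (n_samples, n_latents)
        The shared latent variables, returned so recovery can be scored.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(spec.n_samples)
    latents = rng.standard_normal((n, spec.n_latents))
    blocks = []
    for assign in spec.latent_assignment:
        noise = rng.standard_normal((n, len(assign)))
        data = (spec.signal_weight * latents[:, list(assign)]
                + spec.noise_weight * noise)
        blocks.append(DataBlock.from_array(data))
    return blocks, latents


def split_halves(block: DataBlock) -> Tuple[DataBlock, DataBlock]:
    """Split a block into first-half training and second-half test rows.

    The first ``floor(n/2)`` rows become the training block and the
    remainder the test block; row order is preserved and each half is
    re-centered on its own columns.
    """
    n = block.n_samples
    if n < 2:
        raise ValueError(f"cannot split a block with {n} row(s); need >= 2")
    half = n // 2
    raw = block.raw()
    return (DataBlock.from_array(raw[:half]),
            DataBlock.from_array(raw[half:]))
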