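"""Package-specific error types."""
import numpy as np


class SingularityError(np.linalg.LinAlgError):
    """The generalized eigenproblem's right-hand side is numerically singular.

    Raised when an unregularized fit hits a rank-deficient autocovariance
    (or Gram) block; setting ``reg > 0`` makes the problem well posed.
    """


class CorruptArchiveError(RuntimeError):
    """A model archive is unreadable or missing a required group."""


class UnsupportedVersionError(CorruptArchiveError):
    """A model archive was written with an unknown format version."""
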