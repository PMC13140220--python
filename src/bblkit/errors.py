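"""Exception hierarchy shared across the package."""


class BblkitError(Exception):
    """Base class for all package errors."""


class InputError(BblkitError):
    """Invalid or missing user input (bad ids, empty files, out-of-range offsets)."""


class AlignmentError(BblkitError):
    """Alignment invariant violated (ragged lengths, duplicate ids)."""


class AlphabetError(BblkitError):
    """Sequence contains characters outside the declared alphabet."""


class FrameError(BblkitError):
    """Sequence length incompatible with the reading frame."""


class MappingError(BblkitError):
    """Reference-coordinate mapping failure."""


class NumericalError(BblkitError):
    """Non-finite likelihoods or other numerical breakdown."""


class UnresolvedAmbiguityError(BblkitError):
    """An ambiguous site could not be resolved under the configured policy."""


class ConvergenceWarning(UserWarning):
    """Optimizer stopped before meeting the convergence tolerance."""
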