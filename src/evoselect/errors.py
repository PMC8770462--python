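"""Named exceptions and warnings raised across the package."""


class EvoselectError(Exception):
    """Base class for all package errors."""


class DuplicateFeatureNameError(EvoselectError):
    """A feature table declares the same column name twice."""


class NonNumericValueError(EvoselectError):
    """A feature cell could not be parsed as a finite number."""


class MissingValueError(EvoselectError):
    """A feature table contains missing values (no imputation is performed)."""


class SingleClassLabelError(EvoselectError):
    """The label column does not contain exactly two distinct values."""


class InvalidCorrelationError(EvoselectError):
    """Requested correlation does not yield a valid positive-definite structure."""


class InvalidSplitError(EvoselectError):
    """Split specification is infeasible (empty side or class with < 2 members)."""


class EmptyGroupError(EvoselectError):
    """A statistical test received an empty group."""


class ConstantFeatureWarning(UserWarning):
    """A training-split feature had zero variance and was mapped to zeros."""
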