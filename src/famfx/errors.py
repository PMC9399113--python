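"""Exception types shared across the package."""


class FamfxError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(FamfxError, ValueError):
    """A scenario or function parameter is outside its admissible range."""


class StructuralError(FamfxError, ValueError):
    """Input data violate a structural requirement (e.g. unbalanced sexes,
    missing parents, empty analysis group)."""


class DegenerateInputError(FamfxError, ValueError):
    """An operation received an input that is formally valid but degenerate
    (e.g. standardizing a constant, all-zero weight vector)."""


class AlignmentError(FamfxError, ValueError):
    """SNP sets or effect alleles of dosages and weights cannot be aligned."""


class SingularityError(FamfxError, ValueError):
    """The regression design matrix is rank deficient."""

    def __init__(self, message, columns=None):
        super().__init__(message)
        self.columns = list(columns) if columns is not None else []
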