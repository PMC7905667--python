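"""Exception hierarchy used across the package."""


class PleioPLSError(Exception):
    """Base class for all package errors."""


class DataFormatError(PleioPLSError):
    """Malformed input file (duplicate identifiers, bad shape, ...)."""


class IdentifierError(PleioPLSError):
    """A map or query references an unknown sample/variable/study id."""


class PartitionError(PleioPLSError):
    """Study or group assignments do not form a valid partition."""


class ParameterError(PleioPLSError):
    """Invalid numeric parameter (negative threshold, bad case id, ...)."""


class TieError(PleioPLSError):
    """Tied group norms make an exact group count unattainable."""

    def __init__(self, message, tied_groups=()):
        super().__init__(message)
        self.tied_groups = tuple(tied_groups)


class DegenerateSolutionError(PleioPLSError):
    """The penalty zeroed every loading column."""


class RankDegeneracyError(PleioPLSError):
    """Deflation scores vanished for a nonzero loading."""


class StratificationError(PleioPLSError):
    """Requested stratified folds cannot be constructed."""


class ImputationError(PleioPLSError):
    """A column has no observed value within an imputation stratum."""
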