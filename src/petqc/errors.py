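"""Exception hierarchy."""


class PetQCError(Exception):
    """Base class for all petqc errors."""


class FormatError(PetQCError, ValueError):
    """Malformed input file (bad line, missing columns)."""


class ContractError(PetQCError, RuntimeError):
    """An internal precondition was violated (e.g. grid mismatch)."""


class NothingToScoreError(PetQCError):
    """No filtered PETs survive the span filter; carries the library stats.

    Attributes
    ----------
    stats : LibraryStats
        Counts computed before the pipeline gave up.
    """

    def __init__(self, message, stats=None):
        super().__init__(message)
        self.stats = stats


class UndefinedScoreError(PetQCError):
    """A quality score is undefined (e.g. denQC.50 = 0); carries partials.

    Attributes
    ----------
    partial : dict
        Whatever indicators could still be computed.
    """

    def __init__(self, message, partial=None):
        super().__init__(message)
        self.partial = partial or {}
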