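"""Exception hierarchy shared across the package."""


class HpagtwrError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(HpagtwrError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(HpagtwrError):
    """A configuration file or object is incomplete or inconsistent."""


class TrainingError(HpagtwrError):
    """Embedding training cannot proceed (empty corpus, empty vocabulary...)."""


class LookupError_(HpagtwrError, KeyError):
    """A requested word or key is missing from a vocabulary or table."""


class SingularityError(HpagtwrError):
    """A (weighted) design matrix is singular or numerically near-singular."""

    def __init__(self, message: str, focal: int | None = None):
        super().__init__(message)
        self.focal = focal


class BandwidthError(HpagtwrError):
    """Bandwidth too small (trace(S) close to n) or no valid bandwidth found."""


class UndefinedStatisticError(HpagtwrError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class ParseError(HpagtwrError):
    """A file does not match the expected schema; message names the problem."""
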