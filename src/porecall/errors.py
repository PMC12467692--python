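"""Exception hierarchy.

Every error raised on bad user input or a violated contract derives from
:class:`PorecallError`, so callers (and the CLI) can catch one base class.
"""


class PorecallError(Exception):
    """Base class for all porecall errors."""


class InvalidAlphabetError(PorecallError, ValueError):
    """A sequence or k-mer contains a character outside {A, C, G, T}."""


class UnsupportedKError(PorecallError, ValueError):
    """Requested k-mer length is outside the supported range."""


class IncompleteModelError(PorecallError, ValueError):
    """A pore-model table is missing at least one k-mer."""


class DuplicateKmerError(PorecallError, ValueError):
    """A pore-model table lists the same k-mer more than once."""


class InvalidParameterError(PorecallError, ValueError):
    """A numeric parameter is outside its valid domain (e.g. sigma <= 0)."""


class InvalidDistributionError(PorecallError, ValueError):
    """Transition category probabilities do not form a distribution."""


class InvalidTransitionError(PorecallError, ValueError):
    """A state pair is not connected in the transition structure."""


class EmptyInputError(PorecallError, ValueError):
    """An operation received an empty event vector or chunk."""


class ConfigurationError(PorecallError, ValueError):
    """Inconsistent component configuration (e.g. model k != transitions k)."""


class CorruptedTrellisError(PorecallError, RuntimeError):
    """Traceback hit a missing pointer before reaching the first event."""


class InvalidPathError(PorecallError, ValueError):
    """Consecutive states in a path are not stay/step/skip compatible."""


class DegenerateSignalError(PorecallError, ValueError):
    """Clean signal has zero variance; SNR-scaled noise is undefined."""


class InvalidLengthError(PorecallError, ValueError):
    """Requested sequence length is not positive."""


class InvalidReferenceError(PorecallError, ValueError):
    """Accuracy was requested against an empty reference sequence."""
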