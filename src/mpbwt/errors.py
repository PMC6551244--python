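"""Exception hierarchy for mpbwt.

All library-raised errors derive from :class:`MPBWTError` so callers can
catch data/format problems without swallowing programming errors.
"""


class MPBWTError(Exception):
    """Base class for all mpbwt errors."""


class PanelFormatError(MPBWTError):
    """A panel file (allele matrix or VCF) is malformed."""


class AlphabetViolationError(MPBWTError):
    """An allele code is outside the declared per-site alphabet."""


class ContainerFormatError(MPBWTError):
    """A compressed .mpbwt container is malformed, truncated or corrupt."""


class ParameterError(MPBWTError, ValueError):
    """A caller-supplied parameter is out of range."""
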