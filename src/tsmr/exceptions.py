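"""Exception hierarchy.

``ConfigError`` maps to CLI exit code 2, ``InsufficientInstrumentsError``
to exit code 3; everything else is a plain failure (exit 1).
"""


class TsmrError(Exception):
    """Base class for all package errors."""


class ConfigError(TsmrError):
    """Invalid or incomplete user configuration (bad dialect, missing file...)."""


class DialectError(ConfigError):
    """A required column role is absent from the input under the chosen dialect."""


class ValidationError(TsmrError):
    """Input data violates a stated invariant."""


class InsufficientInstrumentsError(TsmrError):
    """Fewer instruments survive filtering than the requested method needs."""


class UndefinedRatioError(TsmrError):
    """A Wald ratio is requested for a SNP with zero exposure effect."""


class CollinearityError(TsmrError):
    """Rank-deficient multivariable design matrix."""
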