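"""Exception hierarchy shared by all analysis stages."""


class TandemRRMError(Exception):
    """Base class for all package errors."""


class FormatError(TandemRRMError):
    """An input file does not conform to its declared format."""


class EmptyInputError(TandemRRMError):
    """An input that must be non-empty is empty."""


class ConfigurationError(TandemRRMError):
    """A parameter value is outside its allowed range."""


class InputError(TandemRRMError):
    """Input data are structurally invalid for the requested operation."""


class TopologyError(TandemRRMError):
    """A molecular topology cannot be built (e.g. chain break)."""


class IntegrationError(TandemRRMError):
    """Numerical integration diverged."""


class FitError(TandemRRMError):
    """A model fit failed to converge."""


class DegenerateInputError(TandemRRMError):
    """Input is degenerate for the algorithm (e.g. no histogram overlap)."""


class NormalizationError(TandemRRMError):
    """A series cannot be normalized (zero reference intensity)."""
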