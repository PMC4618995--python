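"""Exception hierarchy for cnvrscan."""


class CnvrScanError(Exception):
    """Base class for all cnvrscan errors."""


class ValidationError(CnvrScanError):
    """Inputs are structurally inconsistent (chromosome mismatch, bad table shape...)."""


class InvalidParameterError(ValidationError):
    """A parameter is outside its documented range."""


class DegenerateInputError(CnvrScanError):
    """Input is valid but too degenerate for the operation (too few values, all zero...)."""


class PlacementError(CnvrScanError):
    """Simulated feature placement failed after bounded retries."""


class ConfigurationError(CnvrScanError):
    """A required input (e.g. a GC track) is missing for the requested stage."""
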