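"""Exception hierarchy for etsdyn."""


class EtsdynError(Exception):
    """Base class for all etsdyn errors."""


class ValidationError(EtsdynError, ValueError):
    """Invalid input data or parameters."""


class FittingError(EtsdynError, RuntimeError):
    """Nonlinear fit failed to converge or produced a degenerate solution."""


class DetectionError(EtsdynError, RuntimeError):
    """No band/peak could be detected above the noise floor."""


class ParseError(EtsdynError, ValueError):
    """Malformed input file."""
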