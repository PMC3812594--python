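"""Exception hierarchy for the ebis package."""


class EbisError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(EbisError, ValueError):
    """An input violates a documented invariant (bad parameters, malformed tree...)."""


class DegenerateInputError(EbisError, ValueError):
    """Input is structurally valid but makes the requested quantity undefined
    (e.g. zero-magnitude impedance point, dispersion-free Cole parameters)."""


class InsufficientDataError(EbisError, ValueError):
    """Too few frequency points, or too narrow a span, to support the operation."""


class PairingError(EbisError, ValueError):
    """Central and lateral measurement lists cannot be paired one-to-one."""


class TuningError(EbisError, ValueError):
    """Threshold tuning is impossible (e.g. single-class training set)."""


class ParseError(EbisError, ValueError):
    """A file does not conform to the expected dialect; message names row/column."""
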