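"""Package-wide exception types."""


class ViscofitError(Exception):
    """Base class for all viscofit errors."""


class DomainError(ViscofitError, ValueError):
    """An argument lies outside the physically meaningful domain."""


class UnsupportedConversionError(ViscofitError, ValueError):
    """Requested model interconversion has no closed form."""


class NonUniformGridError(ViscofitError, ValueError):
    """Time grid is not uniform; resample before calling."""


class NoContactError(ViscofitError, ValueError):
    """No tip-sample contact point could be detected."""


class DegenerateInputError(ViscofitError, ValueError):
    """Input carries no usable signal (e.g. all-zero indentation)."""
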