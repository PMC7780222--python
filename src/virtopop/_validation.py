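"""Shared exception types."""


class InvalidParameterError(ValueError):
    """A parameter violates a model admissibility constraint."""


class NumericalFailureError(RuntimeError):
    """A numerical routine diverged or produced non-finite values."""
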