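"""Domain-specific error types."""


class ImplantHeatError(Exception):
    """Base class for package errors."""


class ValidationError(ImplantHeatError, ValueError):
    """Invalid input data or configuration."""


class DegenerateEnvelopeError(ValidationError):
    """RF envelope integrates to zero: the flip angle is unreachable."""


class UnderspecifiedSequenceError(ValidationError):
    """Sequence declares neither an RF pulse train nor a B1+ rms value."""


class ResampleRequiredError(ValidationError):
    """Sampled gradient waveform is not uniformly sampled."""


class SolverError(ImplantHeatError, RuntimeError):
    """A numerical solve failed to converge."""
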