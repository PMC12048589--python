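"""Exception hierarchy shared across the package."""


class RacasError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(RacasError, ValueError):
    """Invalid parameters, malformed files, or broken invariants in inputs."""


class SessionCompleteError(RacasError):
    """Raised when the scheduler is asked to allocate past trial 100."""


class DegenerateInputError(RacasError, ValueError):
    """Statistical input with no usable variance (e.g. constant sample)."""
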