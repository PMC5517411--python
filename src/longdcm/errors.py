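"""Exception hierarchy shared across the package.

User-facing errors split into validation (bad inputs / config) and compute
(numerical failure during a run) so the CLI can map them to exit codes.
"""


class LongdcmError(Exception):
    """Base class for all package errors."""


class ValidationError(LongdcmError, ValueError):
    """Invalid input, configuration, or precondition violation."""


class StabilityError(ValidationError):
    """A connectivity matrix is not stable (some eigenvalue has Re >= 0)."""


class GenerationError(LongdcmError, RuntimeError):
    """Synthetic-cohort generation could not satisfy its constraints."""


class ComputeError(LongdcmError, RuntimeError):
    """A numerical procedure failed (non-finite objective, no progress...)."""
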