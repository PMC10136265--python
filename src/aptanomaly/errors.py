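"""Exception hierarchy.

All user-facing failures derive from :class:`AptanomalyError` so callers (and
the CLI) can distinguish validation problems (bad inputs, broken invariants)
from runtime failures (diverging training, I/O).
"""


class AptanomalyError(Exception):
    """Base class for all package errors."""


class ValidationError(AptanomalyError, ValueError):
    """An input violates a documented invariant; the message names the field."""


class DegenerateSignalError(ValidationError):
    """A signal that cannot be z-scored (constant, or fewer than 2 samples)."""


class DegenerateSampleError(ValidationError):
    """An error sample with zero spread — no bandwidth can be derived."""


class TrainingDivergenceError(AptanomalyError):
    """Training produced a non-finite loss; carries the offending epoch."""

    def __init__(self, epoch: int, loss: float):
        self.epoch = epoch
        self.loss = loss
        super().__init__(f"non-finite training loss ({loss}) at epoch {epoch}")
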