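"""Exception hierarchy for rollgait.

All package-raised errors derive from :class:`RollgaitError` so callers (and
the CLI) can distinguish expected domain failures from genuine bugs.
"""


class RollgaitError(Exception):
    """Base class for all rollgait errors."""


class ParameterError(RollgaitError, ValueError):
    """An invalid configuration or simulation parameter; names the field."""


class FormatError(RollgaitError, ValueError):
    """A file could not be parsed in the expected dialect."""


class DataIntegrityError(RollgaitError, ValueError):
    """Logically inconsistent data, e.g. one dog with conflicting labels."""


class ProcessingError(RollgaitError, RuntimeError):
    """A preprocessing stage produced a degenerate result."""


class ShapeError(RollgaitError, ValueError):
    """An array had the wrong length/shape for the model."""


class SplitError(RollgaitError, ValueError):
    """A subject-level split could not be constructed."""


class TrainingError(RollgaitError, RuntimeError):
    """Optimization failed (e.g. non-finite loss)."""
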