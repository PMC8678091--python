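"""Exception types shared across the pipeline."""


class TaskCoactError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(TaskCoactError, ValueError):
    """A configuration or model parameter violates its invariants."""


class EmptyPhaseError(TaskCoactError, ValueError):
    """A stimulus series was requested for a phase with no trials."""


class DegenerateSeriesError(TaskCoactError, ValueError):
    """A series has zero variance and cannot be z-scored or correlated."""


class DesignError(TaskCoactError, ValueError):
    """The model frame cannot support the requested design (e.g. a
    single-level factor)."""


class GenerationError(TaskCoactError, RuntimeError):
    """The synthetic schedule could not be fitted into the run."""
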