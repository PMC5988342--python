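"""Exception types raised across the analysis pipeline."""


class AttnspaceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AttnspaceError):
    """Invalid simulation or analysis configuration.

    Deliberately not a ValueError subclass: pydantic would swallow it into
    its own ValidationError during model construction.
    """


class DomainError(AttnspaceError, ValueError):
    """Input outside its physical domain (e.g. negative firing rate)."""


class LabelError(AttnspaceError, KeyError):
    """Unknown task / area / decode-space label."""


class DegenerateFitError(AttnspaceError, ValueError):
    """Regression cannot be identified (e.g. all-zero passive responses)."""


class DegenerateGridError(AttnspaceError, ValueError):
    """Duplicate or otherwise unusable interpolation sample angles."""


class EmptyPopulationError(AttnspaceError, ValueError):
    """No cells survive the filters needed to build a population matrix."""


class UndefinedCorrelationError(AttnspaceError, ValueError):
    """Pearson correlation undefined (constant response vector)."""


class DegenerateConfigurationError(AttnspaceError, ValueError):
    """Point configuration unusable for alignment (all points coincident)."""


class UndefinedStressError(AttnspaceError, ZeroDivisionError):
    """Stress undefined: all reference distances are equal."""


class DegenerateHullError(AttnspaceError, ValueError):
    """Convex hull undefined (collinear or too few points)."""


class InsufficientTrialsError(AttnspaceError, ValueError):
    """Too few trials per (cell, stimulus, condition) for resampling."""


class ValidationError(AttnspaceError, ValueError):
    """A trial table is missing required tasks, areas or columns."""


class NoSolutionError(AttnspaceError, ValueError):
    """Power analysis has no admissible solution."""
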