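"""Exception hierarchy shared across the pipeline.

Each stage raises a distinct subclass so the command-line layer can map
failures to distinct exit codes (schema 2, configuration 3, fitting 4,
imputation 5, simulation 6, generic input 7).
"""


class PreScoreError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(PreScoreError):
    """A patient table does not match the documented column dictionary."""

    exit_code = 2


class ConfigurationError(PreScoreError):
    """A generator / pipeline configuration violates its invariants."""

    exit_code = 3


class FittingError(PreScoreError):
    """The Cox model failed to converge or could not be estimated."""

    exit_code = 4


class ImputationError(PreScoreError):
    """Chained-equation imputation cannot proceed (e.g. a fully missing column)."""

    exit_code = 5


class SimulationError(PreScoreError):
    """A responder-enrichment resampling request cannot be satisfied."""

    exit_code = 6


class InputError(PreScoreError):
    """Invalid values passed to an analysis operation."""

    exit_code = 7
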