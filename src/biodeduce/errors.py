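"""Error hierarchy.

Every error carries a stable machine-readable ``code`` so that callers
(and the CLI) can dispatch on failures without parsing messages.
"""

from __future__ import annotations


class BiodeduceError(Exception):
    """Base class; ``code`` is a stable snake_case identifier."""

    code: str = "error"

    def __init__(self, message: str = "", **context):
        super().__init__(message or self.code)
        self.context = context


# ---------------------------------------------------------------- deduction

class IndexOutOfRangeError(BiodeduceError):
    code = "index_out_of_range"


class EmptyAggregateError(BiodeduceError):
    code = "empty_aggregate"


class EmptyEvfListError(BiodeduceError):
    code = "empty_evf_list"


class NoTargetError(BiodeduceError):
    code = "no_target"


class FixpointNotReachedError(BiodeduceError):
    """Fixpoint iteration hit its hard cap; ``partial`` holds the last aggregate."""

    code = "fixpoint_not_reached"

    def __init__(self, message: str = "", partial=None, **context):
        super().__init__(message, **context)
        self.partial = partial


class OracleTooLargeError(BiodeduceError):
    code = "oracle_too_large"


# ----------------------------------------------------------------- kinetics

class NegativeRateError(BiodeduceError):
    code = "negative_rate"


class InvalidReactionError(BiodeduceError):
    code = "invalid_reaction"


class SpeciesMismatchError(BiodeduceError):
    code = "species_mismatch"


class EmptyModelError(BiodeduceError):
    code = "empty_model"


class UnboundParameterError(BiodeduceError):
    code = "unbound_parameter"


class SingularParametersError(BiodeduceError):
    """Raised when a solution's validity assumptions fail; names the predicate."""

    code = "singular_parameters"


class IntegrationFailedError(BiodeduceError):
    code = "integration_failed"


# ------------------------------------------------------------ model library

class UnknownSchemeError(BiodeduceError):
    code = "unknown_scheme"


class NegativeCountError(BiodeduceError):
    code = "negative_count"


class GenerationFailedError(BiodeduceError):
    code = "generation_failed"


# ----------------------------------------------------------------------- io

class InvalidProblemFileError(BiodeduceError):
    code = "invalid_problem_file"


class DistinctnessViolationError(BiodeduceError):
    code = "distinctness_violation"


class UnknownSpeciesError(BiodeduceError):
    code = "unknown_species"


class IoError(BiodeduceError):
    code = "io_error"
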