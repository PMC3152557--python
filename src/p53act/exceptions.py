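"""Exception types raised across the package."""


class P53ActError(Exception):
    """Base class for all package-specific errors."""


class InvalidMutantError(P53ActError, ValueError):
    """A mutant specification violates its invariants."""


class ArityError(P53ActError, ValueError):
    """Number of mutation sites outside 1..4, or mixed arities in one table."""


class MissingStructureError(P53ActError, KeyError):
    """No precomputed structure-feature record for a mutant id."""


class FeatureNameError(P53ActError, ValueError):
    """A feature name does not follow the naming scheme."""


class UnknownFeatureError(P53ActError, KeyError):
    """A requested feature name is not a column of the table."""


class DegenerateVectorError(P53ActError, ValueError):
    """A zero-norm vector reached the cosine distance."""


class EmptyInputError(P53ActError, ValueError):
    """An operation received an empty vector, table or ranking."""


class CapacityError(P53ActError, ValueError):
    """Planted features exceed the dimension of the feature space."""


class PipelineStageError(P53ActError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
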