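"""Exception hierarchy for predsip."""


class PredsipError(Exception):
    """Base class for all predsip errors."""


class ConfigError(PredsipError):
    """Invalid generator or run configuration."""


class UndefinedEstimateError(PredsipError):
    """A per-taxon quantity could not be computed (e.g. all-zero weights)."""


class SaturationError(PredsipError):
    """Taxon AFE at or above the water AFE: growth rate unresolvable."""


class DegenerateFitError(PredsipError):
    """Major-axis fit is degenerate (vertical axis or too few points)."""


class AmbiguousLineageError(PredsipError):
    """A lineage matched more than one predator group."""


class MissingControlError(PredsipError):
    """An effect size references a control group that cannot be resolved."""
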