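"""Exception hierarchy for fragrbe.

Each error class corresponds to a failure mode of the pipeline contracts:
empty fields, mismatched grids, missing stopping-power coverage, malformed
files, violated normalization, unknown species, bad configuration and
infeasible plans.
"""


class FragRBEError(Exception):
    """Base class for all fragrbe errors."""


class EmptyFieldError(FragRBEError):
    """A field has no particles where the operation requires some."""


class GridError(FragRBEError):
    """Depth or energy grids of two objects do not match."""


class CoverageError(FragRBEError):
    """A lookup table does not cover a required (species, energy) entry."""


class FormatError(FragRBEError):
    """A file could not be parsed or declares an unsupported dialect."""


class ValidationError(FragRBEError):
    """File content violates an invariant (e.g. spectrum normalization)."""


class CatalogueError(FragRBEError):
    """A particle species is not in the catalogue or is ill-formed."""


class ConfigError(FragRBEError):
    """A configuration value is out of its allowed domain."""


class InfeasiblePlanError(FragRBEError):
    """The requested target volume cannot be covered by the beam library."""


class ExtrapolationError(FragRBEError):
    """A depth outside the span of a table was requested."""
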