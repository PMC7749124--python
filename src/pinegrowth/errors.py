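"""Exception hierarchy.

Exit-code mapping used by the CLI: validation problems exit 2, model
convergence failures exit 3, I/O failures exit 4.
"""


class PinegrowthError(Exception):
    """Base class for all package errors."""


class DesignError(PinegrowthError):
    """Invalid experimental design configuration (e.g. odd block size)."""


class ConfigurationError(PinegrowthError):
    """Effect or run configuration does not cover the design (names the level)."""


class SchemaError(PinegrowthError):
    """Input table is missing a mandatory column or has an unusable dtype."""


class ValidationError(PinegrowthError):
    """Input records violate a structural invariant that blocks analysis."""


class SingularDesignError(PinegrowthError):
    """A factor cell required by the model is empty (names the cell)."""


class ConvergenceError(PinegrowthError):
    """REML optimisation failed after all restarts."""
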