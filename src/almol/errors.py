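"""Exception types shared across the package."""


class AlmolError(Exception):
    """Base class for all package errors."""


class MoleculeParseError(AlmolError, ValueError):
    """A SMILES string could not be parsed into a valid molecule."""


class DimensionError(AlmolError, ValueError):
    """Vector operands have incompatible lengths."""


class ParameterError(AlmolError, ValueError):
    """A numeric parameter violates its precondition (e.g. low >= high)."""


class ConfigurationError(AlmolError, ValueError):
    """A run or scoring configuration is invalid or incomplete."""


class CapacityError(AlmolError, ValueError):
    """A request exceeds the enumerable size of the fixture library."""


class FitError(AlmolError, ValueError):
    """Model fitting is impossible on the provided data."""


class StateError(AlmolError, RuntimeError):
    """An operation was called on an object in the wrong state."""


class DegenerateDistributionError(AlmolError, ValueError):
    """All candidate weights are zero; no distribution can be formed."""
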