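"""Exception hierarchy shared across pipeline stages."""


class DualScreenError(Exception):
    """Base class for all pipeline errors."""


class InvalidStructure(DualScreenError):
    """A SMILES string could not be parsed into a molecule."""


class SchemaError(DualScreenError):
    """An input table is missing a mandatory column or field."""


class UnitError(DualScreenError):
    """Potency units for a compound cannot be reconciled."""


class SpecError(DualScreenError):
    """Fingerprint specifications are inconsistent (length/name mismatch)."""


class InsufficientData(DualScreenError):
    """Not enough data to perform the requested computation."""


class ConfigError(DualScreenError):
    """A configuration value is invalid or inconsistent."""
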