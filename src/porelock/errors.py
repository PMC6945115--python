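"""Exception hierarchy."""


class PoreLockError(Exception):
    """Base class for all porelock errors."""


class FormatError(PoreLockError):
    """A structure or trajectory file could not be parsed."""


class StructureError(PoreLockError):
    """The molecular assembly does not satisfy a structural precondition
    (e.g. a pentamer is required but a different chain count was found)."""


class MappingError(PoreLockError):
    """A primed pore position could not be mapped onto a residue/Calpha."""


class AxisError(PoreLockError):
    """The channel axis could not be defined or oriented."""


class ConfigurationError(PoreLockError):
    """Inconsistent or incomplete run configuration."""
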