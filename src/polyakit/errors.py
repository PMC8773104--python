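"""Exception types shared across the pipeline."""


class PolyakitError(Exception):
    """Base class for all polyakit errors."""


class ConfigurationError(PolyakitError):
    """A configuration value is invalid; the message names the field."""


class CapacityError(PolyakitError):
    """A simulated genome is too small for the requested gene content."""


class MalformedRecordError(PolyakitError):
    """A sequencing record is internally inconsistent (e.g. seq/qual length)."""


class FormatError(PolyakitError):
    """An input file violates its format contract (SAM/GFF3/...)."""


class ClassificationError(PolyakitError):
    """A genic cluster position falls in no feature interval (assignment bug)."""
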