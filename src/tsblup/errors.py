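"""Exception hierarchy for tsblup."""


class TsblupError(Exception):
    """Base class for all tsblup errors."""


class ParseError(TsblupError):
    """A file could not be parsed (malformed row, bad token, ...)."""


class ValidationError(TsblupError):
    """Data violates an invariant (bad dosage, duplicate id, ...)."""


class AlignmentError(TsblupError):
    """IDs of two objects do not line up; never silently reordered."""


class NonIdentifiableError(TsblupError):
    """Variance components cannot be separated for the given kinship."""
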