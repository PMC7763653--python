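"""Exception hierarchy for the STR profiling pipeline."""


class StrChipError(Exception):
    """Base class for all package-specific errors."""


class PanelValidationError(StrChipError):
    """A panel configuration violates the multiplex-design rules."""


class TraceError(StrChipError):
    """An electropherogram cannot be simulated or parsed as requested."""


class CalibrationError(StrChipError):
    """The ladder trace cannot be turned into a time-to-size calibration."""


class AlignmentError(StrChipError):
    """A sample well lacks the internal-marker peaks needed for alignment."""


class ProfileError(StrChipError):
    """An STR profile is malformed or incompatible with the requested operation."""
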