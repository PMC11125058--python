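"""Exception hierarchy for the metspecs pipeline."""


class MetspecsError(Exception):
    """Base class for all package errors."""


class FormatError(MetspecsError):
    """A raw input file does not match the documented dialect."""


class IntegrityError(MetspecsError):
    """Internally inconsistent data (non-monotone timestamps, overlapping
    segments, manifest/image count mismatch)."""


class ReferenceError_(MetspecsError):
    """A record refers to an entity that does not exist (unknown participant,
    missing steady-state label)."""


class RangeError(MetspecsError):
    """A value lies outside its admissible range (e.g. pixel outside [0, 255])."""


class ConfigError(MetspecsError):
    """An invalid configuration value or combination."""


class DataError(MetspecsError):
    """Non-finite or otherwise unusable sample values."""


class AlignmentError(MetspecsError):
    """Channel groups of unequal length cannot be combined."""


class InsufficientDataError(MetspecsError):
    """Not enough observations for the requested computation."""


class TrainingError(MetspecsError):
    """Optimisation produced non-finite losses."""
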