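"""Package-specific exception types.

Every operation that can fail on bad input raises one of these named errors
rather than a bare ValueError, so callers (and the CLI) can distinguish
user-input problems from genuine bugs.
"""


class TfpbciError(Exception):
    """Base class for all tfpbci errors."""


class UnknownPresetError(TfpbciError):
    """Requested montage preset name is not known."""


class MontageError(TfpbciError):
    """Montage is degenerate or inconsistent with a recording."""


class EffectSpecError(TfpbciError):
    """Class-effect specification is empty or references unknown channels."""


class EdfError(TfpbciError):
    """EDF file is unreadable, truncated, or structurally invalid."""


class ConfigError(TfpbciError):
    """Invalid preprocessing / feature / selection configuration."""


class EpochingError(TfpbciError):
    """Epoching produced no trials or met an unmappable event label."""


class FeatureError(TfpbciError):
    """Invalid input to feature extraction or scaling."""


class SelectionError(TfpbciError):
    """Invalid input to mutual-information feature selection."""


class ClassifierError(TfpbciError):
    """Degenerate training set or invalid classifier configuration."""
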