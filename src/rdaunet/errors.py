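"""Exception taxonomy shared across the package."""

__all__ = [
    "ConfigurationError",
    "ShapeError",
    "InputError",
    "FormatError",
    "UndefinedMetricError",
    "LeakageError",
]


class ConfigurationError(ValueError):
    """An invalid configuration value; the message names the offending field."""


class ShapeError(ValueError):
    """Array shapes incompatible with the operation's contract."""


class InputError(ValueError):
    """Invalid input data (empty sets, non-binary masks, mismatched grids)."""


class FormatError(ValueError):
    """A file or series does not conform to the expected on-disk format."""


class UndefinedMetricError(ValueError):
    """The metric is mathematically undefined for this input (e.g. empty mask)."""


class LeakageError(RuntimeError):
    """Evaluation ids overlap the recorded training split."""
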