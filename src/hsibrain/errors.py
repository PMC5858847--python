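"""Exception hierarchy for the hsibrain pipeline.

Every stage raises a subclass of :class:`HsiError` so callers can catch
pipeline failures without swallowing programming errors.
"""


class HsiError(Exception):
    """Base class for all hsibrain errors."""


class FormatError(HsiError):
    """Malformed file content (e.g. a broken ENVI header field)."""


class DimensionError(HsiError):
    """Array shapes or band counts that do not match."""


class ConfigError(HsiError):
    """Invalid configuration values (empty band range, bad cluster count...)."""


class DegenerateInputError(HsiError):
    """Input too small or too trivial for the requested computation."""


class PaletteError(HsiError):
    """A class id with no palette entry."""


class InvalidClassError(HsiError):
    """A class id outside the known class dictionary (e.g. 0 = unlabeled)."""


class UndefinedAngleError(HsiError):
    """Spectral angle requested against a zero spectrum."""


class TrainingError(HsiError):
    """Supervised training impossible (single class, too few samples...)."""


class StratificationError(HsiError):
    """A class smaller than the requested fold count."""
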