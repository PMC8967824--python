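"""Exception hierarchy.

Every error raised on a user-facing path derives from :class:`SzdpdError` so
callers (and the CLI) can map failures to categories: bad caller input,
unparseable source files, corrupt encoded payloads, or missing entities.
"""


class SzdpdError(Exception):
    """Base class for all errors raised by this package."""


class InvalidInputError(SzdpdError, ValueError):
    """Caller-supplied data violates a precondition (NaN m/z, length mismatch...)."""


class UnsortedInputError(InvalidInputError):
    """An array that must be non-decreasing is not."""


class RangeError(SzdpdError, ValueError):
    """A value exceeds the representable range of a codec stage."""


class CapacityError(InvalidInputError):
    """More spectra offered to a stack than its 2**n layers can hold."""


class FormatError(SzdpdError, ValueError):
    """An encoded payload or metadata file is corrupt or inconsistent."""


class UnsupportedVersionError(FormatError):
    """Metadata declares a format version this reader does not understand."""


class UnsupportedFeatureError(SzdpdError, ValueError):
    """An input file uses a feature outside the supported subset (e.g. Numpress)."""


class ParseError(SzdpdError, ValueError):
    """Source file (mzML) could not be parsed at all."""


class EntityLookupError(SzdpdError, KeyError):
    """A block / stack / spectrum id does not exist in the run."""


class ConfigError(SzdpdError, ValueError):
    """A configuration object is internally inconsistent or out of range."""
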