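"""Exception hierarchy shared across the package.

All admixlocus errors derive from :class:`AdmixLocusError` so callers can
catch the package's failures with a single except clause while CLI code maps
them onto exit codes.
"""


class AdmixLocusError(Exception):
    """Base class for all errors raised by admixlocus."""


class ParseError(AdmixLocusError):
    """A file could not be parsed; the message names the offending line."""


class ValidationError(AdmixLocusError):
    """Parsed data violated an invariant (duplicate positions, bad sums...)."""


class ConsistencyError(AdmixLocusError):
    """Two inputs that must agree (line counts, haplotype sets) do not."""


class ConfigError(AdmixLocusError):
    """A configuration value is missing, malformed, or out of range."""


class MapLookupError(AdmixLocusError):
    """A chromosome is absent from the genetic map, or unusable."""


class SizeError(AdmixLocusError):
    """A request asked for more items than the data can supply."""


class DegenerateInputError(AdmixLocusError):
    """An input is formally valid but carries no usable signal (empty, all-zero)."""
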