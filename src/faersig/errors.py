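"""Exception hierarchy for the pipeline.

All pipeline errors derive from :class:`FaersigError` so callers (and the
CLI) can distinguish configuration problems from malformed input data.
"""


class FaersigError(Exception):
    """Base class for all faersig errors."""


class ConfigError(FaersigError, ValueError):
    """Invalid simulation or run configuration."""


class FormatError(FaersigError, ValueError):
    """Input file is missing, unreadable, or lacks required columns."""


class DataError(FaersigError, ValueError):
    """Input parsed fine but is unusable (e.g. empty corpus)."""
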