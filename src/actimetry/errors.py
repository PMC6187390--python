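"""Exception hierarchy for the actimetry pipeline.

Every stage raises a subclass of :class:`ActimetryError` so the CLI can tag
failures with the stage that produced them and exit non-zero.
"""


class ActimetryError(Exception):
    """Base class for all actimetry errors."""


class FormatError(ActimetryError):
    """A file does not conform to the expected column layout / dialect."""


class DataError(ActimetryError):
    """Input values violate a contract (non-finite, negative AI, duplicates...)."""


class ConfigError(ActimetryError):
    """A configuration value is invalid or inconsistent with the data."""


class AlignmentError(ActimetryError):
    """Two series that must share a time base do not."""


class CoverageError(ActimetryError):
    """A day window is not fully covered and partial data was not allowed."""
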