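"""Exception hierarchy shared across the package.

All user-facing failures derive from :class:`SnailError` so the CLI can
distinguish expected errors (bad input, bad configuration) from bugs.
"""


class SnailError(Exception):
    """Base class for all snailplot errors."""


class InputError(SnailError):
    """A source file or directory is missing, unreadable, or empty."""


class ParseError(SnailError):
    """A file was readable but its content is malformed."""


class ConfigError(SnailError):
    """An option or parameter value is invalid."""


class ConsistencyError(SnailError):
    """Dataset members disagree with each other (e.g. array length vs meta)."""
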