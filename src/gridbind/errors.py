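"""Exception hierarchy.

All errors raised deliberately by the package derive from :class:`GridbindError`
so callers (and the CLI) can distinguish user/data errors from genuine bugs.
"""


class GridbindError(Exception):
    """Base class for all errors raised by gridbind."""


class ParseError(GridbindError):
    """A structure, trajectory or table file could not be parsed."""


class LeakageError(GridbindError):
    """A complex id crosses the train/validation/test boundary."""
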