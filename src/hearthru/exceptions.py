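"""Package-specific error types.

Every error raised on bad user input is a subclass of :class:`HearthruError`
so callers can catch the package's failures in one clause while still
distinguishing configuration problems from degenerate-signal conditions.
"""


class HearthruError(Exception):
    """Base class for all errors raised by hearthru."""


class ConfigurationError(HearthruError, ValueError):
    """A parameter block violates its invariants."""


class GridRangeError(HearthruError, ValueError):
    """A requested direction lies outside the supported angular range."""


class DegenerateSignalError(HearthruError, ValueError):
    """A signal is unusable for the requested measure (e.g. zero energy)."""


class SampleRateError(HearthruError, ValueError):
    """Sample rates of two signals that must match do not."""


class MissingColumnError(HearthruError, KeyError):
    """A required column is absent from a table being read."""

    def __init__(self, column: str, path: str | None = None):
        self.column = column
        where = f" in {path}" if path else ""
        super().__init__(f"required column {column!r} is missing{where}")
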