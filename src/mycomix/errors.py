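"""Exception hierarchy shared across the package.

All domain errors derive from :class:`MycomixError` so callers (and the CLI)
can distinguish data/configuration problems from programming errors.
"""


class MycomixError(Exception):
    """Base class for all mycomix domain errors."""


class InvalidInputError(MycomixError, ValueError):
    """A value violates an operation's preconditions (non-finite delta,
    non-positive isotope ratio, empty sequence, ...)."""


class MissingReferenceError(MycomixError):
    """A plot contains target plants but no autotrophic reference plants,
    so no plot-wise baseline can be formed."""

    def __init__(self, plot_id: str, message: str | None = None):
        self.plot_id = plot_id
        super().__init__(
            message or f"plot {plot_id!r} has target samples but no reference samples"
        )


class ConfigurationError(MycomixError):
    """Run configuration is inconsistent (unknown baseline group, group
    referencing an undefined site, ...)."""


class ParseError(MycomixError):
    """An input file could not be parsed; carries the 1-based line number
    when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
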