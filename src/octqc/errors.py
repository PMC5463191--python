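"""Exception hierarchy for octqc."""


class OCTQCError(Exception):
    """Base class for all octqc errors."""


class ConfigurationError(OCTQCError):
    """Invalid scene, noise, design or run configuration."""


class FormatError(OCTQCError):
    """A file does not match its declared schema."""


class BoundaryOrderError(FormatError):
    """Boundary curves cross; carries the first offending column."""

    def __init__(self, column: int, message: str | None = None):
        self.column = column
        super().__init__(
            message or f"boundary ordering violated at column {column}"
        )


class DegenerateRegionError(OCTQCError):
    """A layer region is empty or has zero variance where variance is required."""
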