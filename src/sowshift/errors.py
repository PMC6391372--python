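"""Exception types shared across the pipeline."""


class SowshiftError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(SowshiftError):
    """A table is missing required columns or has malformed ones."""


class ValidationError(SowshiftError):
    """A table parsed, but one or more values violate an invariant."""


class MissingDaysError(ValidationError):
    """A daily-weather series does not cover the required sowing-relative span."""

    def __init__(self, missing_offsets, message=None):
        self.missing_offsets = sorted(missing_offsets)
        if message is None:
            message = (
                f"daily series has {len(self.missing_offsets)} missing "
                f"sowing-relative day offsets: {self.missing_offsets[:10]}"
                + ("..." if len(self.missing_offsets) > 10 else "")
            )
        super().__init__(message)
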