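"""Exception types shared across the pipeline."""


class NeoresponseError(Exception):
    """Base class for all package errors."""


class ValidationError(NeoresponseError, ValueError):
    """An input value violates a documented precondition."""


class ConfigError(NeoresponseError, ValueError):
    """A cohort/pipeline configuration field is invalid; names the field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"config field '{field}': {message}")


class DataError(NeoresponseError, ValueError):
    """A table violates its schema (missing column, duplicate key, bad row)."""


class ManifestError(NeoresponseError, FileNotFoundError):
    """Required input tables are missing from a cohort directory."""

    def __init__(self, missing: list[str]):
        self.missing = list(missing)
        super().__init__("missing required tables: " + ", ".join(self.missing))
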