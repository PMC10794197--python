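"""Exception hierarchy shared across the pipeline."""


class TadfMinerError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TadfMinerError):
    """Invalid or missing configuration (unknown dialect, tagger, backend...)."""


class MarkupParseError(TadfMinerError):
    """Malformed input markup; carries the source line when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class SmilesParseError(TadfMinerError):
    """Structurally invalid SMILES (unbalanced brackets, unpaired ring bonds)."""


class UnitError(TadfMinerError):
    """Unit not allowed by the property model; names the offending unit."""

    def __init__(self, unit: str, property_id: str):
        self.unit = unit
        self.property_id = property_id
        super().__init__(f"unit {unit!r} is not valid for property {property_id!r}")


class SchemaValidationError(TadfMinerError):
    """Record fails the database schema; lists offending fields."""

    def __init__(self, message: str, fields: list[str] | None = None):
        self.fields = fields or []
        if self.fields:
            message = f"{message}: {', '.join(self.fields)}"
        super().__init__(message)
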