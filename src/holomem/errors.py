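"""Exception hierarchy shared by every stage of the pipeline."""


class HolomemError(Exception):
    """Base class for all package errors."""


class ParseError(HolomemError):
    """An input file violates its declared dialect (carries file/line context)."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        where = ""
        if path is not None:
            where = f" [{path}" + (f":{line}" if line is not None else "") + "]"
        super().__init__(message + where)


class DataError(HolomemError):
    """Input parses but violates a semantic contract (e.g. cut site past end)."""


class ConfigurationError(HolomemError):
    """A configuration value is outside its documented domain."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")
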