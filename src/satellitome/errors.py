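"""Exception hierarchy.

Exit-code mapping used by the CLI: configuration problems exit 2, data
problems exit 3 (see :mod:`satellitome.cli`).
"""


class SatellitomeError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(SatellitomeError, ValueError):
    """A simulation or planted-family specification violates its contract."""


class InvalidInputError(SatellitomeError, ValueError):
    """An operation received an argument outside its documented domain."""


class ConfigError(SatellitomeError):
    """A run configuration is incomplete or inconsistent (CLI exit code 2)."""


class DataError(SatellitomeError):
    """Input data could not be used (CLI exit code 3)."""


class ParseError(DataError):
    """A catalog or table file is malformed; carries the offending line."""

    def __init__(self, message: str, path: str | None = None,
                 line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class EmptyCatalogError(DataError):
    """An operation that needs at least one family got an empty catalog."""
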