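"""Exception hierarchy.

Three broad classes map to the CLI's exit codes: configuration errors (bad
flags / config file), data errors (malformed or inconsistent input), and
computation errors (model domain violations and the like).
"""


class BarcodeKitError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(BarcodeKitError):
    """Invalid configuration or parameters."""


class DataError(BarcodeKitError):
    """Malformed or inconsistent input data."""


class FastaParseError(DataError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class DuplicateIdError(DataError):
    """Two records share an accession id."""


class HeaderError(DataError):
    """A FASTA header does not match the label spec."""


class ComputationError(BarcodeKitError):
    """A numeric computation failed (domain violation etc.)."""


class SaturationError(ComputationError):
    """Distance-model log argument out of domain (sequences too diverged)."""


class NoComparableSitesError(ComputationError):
    """A sequence pair shares no comparable (gap-free, unambiguous) sites."""
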