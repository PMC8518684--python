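"""Exception hierarchy."""


class CageScreenError(Exception):
    """Base class for all package errors."""


class ParseError(CageScreenError):
    """A SMILES string or input file could not be parsed."""


class ValidationError(CageScreenError):
    """An input violates a structural precondition."""


class EmbeddingError(CageScreenError):
    """3D embedding of a ligand failed after bounded retries."""


class SiteDetectionError(CageScreenError):
    """PdN4 coordination sites could not be identified."""


class BackendUnavailableError(CageScreenError):
    """A requested external optimizer/energy executable is not installed."""


class XYZFormatError(CageScreenError):
    """A coordinate file is malformed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)
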