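"""Exception hierarchy shared across vennkit.

Every error class carries a distinct process exit code so the command-line
front end can map failures to machine-checkable statuses.
"""


class VennKitError(Exception):
    """Base class for all vennkit errors."""

    exit_code = 1


class DocumentError(VennKitError):
    """Malformed or inconsistent input document (JSON series, CSV, SVG)."""

    exit_code = 4


class AmbiguousFormatError(DocumentError):
    """Document carries signals of more than one input format."""

    exit_code = 4


class ListLimitError(VennKitError):
    """More than six lists were supplied; diagrams support at most six."""

    exit_code = 5


class EmptyInputError(VennKitError):
    """No usable input (e.g. every plain-text list blob is empty)."""

    exit_code = 3


class ExportUnsupportedError(VennKitError):
    """Requested export needs element membership that the input lacks."""

    exit_code = 6


class QueryError(VennKitError):
    """Invalid search query (empty or unusable)."""

    exit_code = 2
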