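"""Exception hierarchy for the mdsfs package."""


class MDSFSError(Exception):
    """Base class for all package errors."""


class TableFormatError(MDSFSError):
    """An attribute table file violates the expected layout or invariants."""


class UnknownSymbolError(MDSFSError, KeyError):
    """An attribute symbol is not present in the table (symbols are case-sensitive)."""


class DuplicateSymbolError(MDSFSError):
    """A subset string or table repeats an attribute symbol."""


class DegenerateInputError(MDSFSError, ValueError):
    """Input is structurally valid but empty or otherwise carries no information."""
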