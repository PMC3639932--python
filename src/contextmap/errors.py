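"""Exception hierarchy for contextmap."""


class ContextmapError(Exception):
    """Base class for all contextmap errors."""


class CapabilityError(ContextmapError):
    """A requested operation needs data or a backend that is unavailable
    (e.g. a genome loaded without sequence, or a missing rasterizer)."""


class ParseError(ContextmapError):
    """Malformed user input (region lines, tables, Newick text)."""

    def __init__(self, message, line=None, offset=None):
        self.line = line
        self.offset = offset
        where = ""
        if line is not None:
            where = f" (line {line})"
        elif offset is not None:
            where = f" (offset {offset})"
        super().__init__(message + where)


class AmbiguousIdentifierError(ContextmapError):
    """An identifier resolves to more than one gene across the loaded genomes."""


class TranslationError(ContextmapError):
    """On-the-fly translation hit an internal stop codon or a bad frame."""
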