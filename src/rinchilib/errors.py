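"""Exception hierarchy for reaction-identifier processing."""


class RInChIError(Exception):
    """Base class for all errors raised by this package."""


class MolfileParseError(RInChIError):
    """A CTAB V2000 block could not be parsed.

    ``line`` is the 1-based line number within the molfile at which the
    problem was detected (0 when no specific line can be blamed).
    """

    def __init__(self, message: str, line: int = 0):
        super().__init__(message)
        self.line = line


class InChIConversionError(RInChIError):
    """The InChI engine failed to produce an identifier for a structure."""

    def __init__(self, message: str, engine_message: str = ""):
        super().__init__(message)
        self.engine_message = engine_message


class InChIDecodeError(RInChIError):
    """An InChI string could not be converted back into a structure."""


class LayerParseError(RInChIError):
    """An InChI layer has malformed syntax. ``layer`` names the offender."""

    def __init__(self, message: str, layer: str = ""):
        super().__init__(message)
        self.layer = layer


class RXNFormatError(RInChIError):
    """An RXNfile violates the MDL format.

    ``molfile_index`` is the 0-based index of the embedded molfile at
    which the problem occurred, or -1 for header-level problems.
    """

    def __init__(self, message: str, molfile_index: int = -1):
        super().__init__(message)
        self.molfile_index = molfile_index


class RDFileError(RInChIError):
    """An RDfile record could not be processed. ``record_index`` is 0-based."""

    def __init__(self, message: str, record_index: int = -1):
        super().__init__(message)
        self.record_index = record_index


class RInChIValidationError(RInChIError):
    """A reaction-identifier string violates the grammar.

    ``rule`` names the violated construction rule, e.g. ``"header"``,
    ``"direction"`` or ``"group-order"``.
    """

    def __init__(self, message: str, rule: str = ""):
        super().__init__(message)
        self.rule = rule


class OrientationError(RInChIError):
    """A multistep sequence contains a step whose direction cannot be
    resolved into reactants-before-products order."""
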