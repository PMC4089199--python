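"""Exception hierarchy for protsel.

All data/validation problems raise :class:`ProtselError` subclasses so the
CLI can map them uniformly to exit code 1, keeping exit code 2 for usage
errors.
"""


class ProtselError(Exception):
    """Base class for all protsel data and validation errors."""


class FastaParseError(ProtselError):
    """Malformed FASTA input; carries the offending line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class NonStandardResidueError(ProtselError):
    """A sequence contains residues outside the 20-letter alphabet under policy 'reject'."""


class DatasetError(ProtselError):
    """Invalid labeled dataset (duplicate ids, missing ids, degenerate classes...)."""


class ParameterError(ProtselError):
    """A parameter is outside its documented range."""


class DegenerateClassError(ProtselError):
    """A class has fewer than 2 sequences, so the sample variance is undefined."""


class ShapeError(ProtselError):
    """Mismatched vector/matrix shapes between operands."""


class GenerationError(ProtselError):
    """Synthetic-data generation could not satisfy the requested configuration."""
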