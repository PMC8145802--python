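"""Exception types shared across the package."""


class IsoQuantBenchError(Exception):
    """Base class for package-specific errors."""


class GtfParseError(IsoQuantBenchError):
    """Raised for malformed or rejected GTF records; messages name the line."""


class CoordinateError(IsoQuantBenchError):
    """An interval falls outside its chromosome, or an exon set is invalid."""


class UndefinedPropertyError(IsoQuantBenchError):
    """A sequence property is undefined for the given input (e.g. too short)."""


class DialectError(IsoQuantBenchError):
    """A table's column layout does not match the requested dialect."""


class TruthAnnotationMismatchError(IsoQuantBenchError):
    """An expressed transcript in the truth table is absent from the annotation."""


class ValidationError(IsoQuantBenchError):
    """A value violates a documented invariant (e.g. q-value outside [0, 1])."""
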