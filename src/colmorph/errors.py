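"""Exception hierarchy for colmorph."""


class ColmorphError(Exception):
    """Base class for all colmorph errors."""


class InvalidSpecificationError(ColmorphError, ValueError):
    """A filament or image specification violates its invariants."""


class PlacementError(ColmorphError, RuntimeError):
    """A filament polyline violates margin or separation constraints."""


class EmptyInputError(ColmorphError, ValueError):
    """An operation that needs at least one element received none."""


class UndefinedLengthError(ColmorphError, ValueError):
    """Arc length requested for a centerline with fewer than two points."""


class MeasurementRefusedError(ColmorphError, ValueError):
    """A QC-flagged centerline was measured without an explicit override."""


class AssayError(ColmorphError, ValueError):
    """Plate-assay inputs are degenerate (zero denominator, missing control,
    incomplete qPCR table)."""
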