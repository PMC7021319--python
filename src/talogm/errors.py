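"""Exception hierarchy for talogm."""


class TalogmError(ValueError):
    """Base class for all structured talogm errors."""


class TemplateError(TalogmError):
    """Template topology violates its invariants."""


class DatasetError(TalogmError):
    """A specimen table or dataset is malformed."""


class DegenerateGeometryError(TalogmError):
    """A point configuration is too degenerate for the requested operation
    (coplanar TPS source, zero centroid size, rank-deficient rotation fit...)."""


class MissingPointsError(TalogmError):
    """An operation that requires complete configurations met missing points,
    or a fragment retains too few points to work with."""
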