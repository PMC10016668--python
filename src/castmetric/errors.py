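"""Exception hierarchy for castmetric."""


class CastMetricError(Exception):
    """Base class for all castmetric errors."""


class MeshFormatError(CastMetricError):
    """An STL file is malformed; the message names the offending byte offset or line."""


class ParameterError(CastMetricError, ValueError):
    """A parameter is outside its documented domain."""


class DegenerateGeometryError(CastMetricError):
    """Too few or degenerate (e.g. collinear) points for a geometric estimate."""


class AlignmentError(CastMetricError):
    """Rigid registration failed, e.g. no surviving correspondences."""


class EmptyResultError(CastMetricError):
    """An operation produced an empty mesh or deviation field."""
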