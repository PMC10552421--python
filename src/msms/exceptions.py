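"""Exception hierarchy shared across the msms modules."""


class MsmsError(Exception):
    """Base class for all msms errors."""


class SchemaError(MsmsError):
    """An input table is missing required columns or has malformed rows."""


class ConfigurationError(MsmsError):
    """A parameter value is invalid (non-positive threshold, bad matrix...)."""


class GeometryError(MsmsError):
    """A boundary polygon or other geometry is invalid."""


class InsufficientDataError(MsmsError):
    """Too few observations to run the requested estimator."""


class DegenerateDataError(MsmsError):
    """Data carry no information for the estimator (all-identical values...)."""


class UndefinedMetricError(MsmsError):
    """The metric is undefined for this input (e.g. zero-length path)."""
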