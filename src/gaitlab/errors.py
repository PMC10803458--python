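"""Exception hierarchy for gaitlab.

Each family maps to a distinct CLI exit code (see :mod:`gaitlab.cli`).
"""


class GaitlabError(Exception):
    """Base class for all gaitlab errors."""


class ConfigurationError(GaitlabError):
    """Invalid configuration value; message names the offending field."""


class FormatError(GaitlabError):
    """A file does not match the documented trajectory/profile dialect."""


class TrajectoryParseError(FormatError):
    """A cell could not be parsed; message carries the row number."""


class DegenerateGeometryError(GaitlabError):
    """Zero-length segment or collinear landmarks; message carries the frame index."""


class OrderingError(GaitlabError):
    """Step times are not strictly increasing."""


class EmptyInputError(GaitlabError):
    """An operation received an empty series."""


class NoGaitDetectedError(GaitlabError):
    """No gait events could be found in the signal."""


class UndefinedStatisticError(GaitlabError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class PairingError(GaitlabError):
    """Gold/test trajectory sets could not be paired."""


class SchemaError(GaitlabError):
    """A parameter table is missing required columns."""
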