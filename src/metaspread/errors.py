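"""Exception hierarchy for the metaspread pipeline.

All pipeline-specific failures derive from :class:`MetaspreadError` so
callers (and the batch driver) can distinguish analysis failures from
programming errors.
"""


class MetaspreadError(Exception):
    """Base class for all metaspread errors."""


class AmbiguousChannelError(MetaspreadError):
    """A channel token matched zero or more than one file."""


class ShapeMismatchError(MetaspreadError):
    """Rasters that must share a pixel grid do not."""


class FormatError(MetaspreadError):
    """A file's contents violate the expected format (e.g. negative labels)."""


class MissingLabelError(MetaspreadError, KeyError):
    """An operation referenced an instance label absent from the mask."""


class CapacityError(MetaspreadError):
    """Synthetic object placement failed after the retry budget."""


class BackendContractError(MetaspreadError):
    """A segmentation backend returned output violating the adapter contract."""


class ModelUnavailableError(MetaspreadError):
    """No learned segmentation backend is configured."""


class NormalizationError(MetaspreadError):
    """Intensity normalization is undefined (missing or zero-mean control)."""


class StatisticsError(MetaspreadError):
    """A statistical comparison was requested on degenerate groups."""


class ConsolidationError(MetaspreadError):
    """Tables with incompatible schemas cannot be consolidated."""


class ConfigError(MetaspreadError):
    """A run configuration is invalid or cannot be parsed."""


class EmptyInputError(MetaspreadError):
    """A batch run found no complete field of view to process."""
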