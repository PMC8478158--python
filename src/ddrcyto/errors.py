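"""Exception hierarchy for the pipeline.

Every stage raises a subclass of :class:`DdrCytoError` so the CLI can map
failures onto its exit-code contract (3 = data error, 4 = configuration
error) without string matching.
"""


class DdrCytoError(Exception):
    """Base class for all pipeline errors."""


class DataError(DdrCytoError):
    """Problems with input data (exit code 3)."""


class ConfigError(DdrCytoError):
    """Problems with configuration (exit code 4)."""


class FcsFormatError(DataError):
    """Malformed FCS header or TEXT segment; names the offending keyword."""


class TruncationError(DataError):
    """DATA segment shorter than the event count promised by the header."""


class ValidationError(DataError):
    """Invalid values passed to a writer or statistic (e.g. NaN intensities)."""


class PanelError(DataError):
    """A required channel/role is missing from the panel."""


class StateError(DdrCytoError):
    """Operation applied in the wrong pipeline state (e.g. double arcsinh)."""


class EstimationError(DataError):
    """Threshold estimation impossible (too few events, constant channel)."""


class GatingSpecError(ConfigError):
    """A population definition references an unavailable marker or threshold."""


class ManifestError(ConfigError):
    """Sample label absent from the experiment manifest."""


class MissingReferenceError(DataError):
    """No untreated (time-0) reference sample for a donor."""
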