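"""Exception hierarchy for dvhscore."""


class DvhScoreError(Exception):
    """Base class for all dvhscore errors."""


class GeometryMismatch(DvhScoreError):
    """Two volumes that must share a grid geometry do not."""


class EmptyStructure(DvhScoreError):
    """A structure with zero volume was used where volume is required."""


class VolumeExceedsStructure(DvhScoreError):
    """A percent volume request outside (0, 100] of the structure."""


class UnrecognizedMetricText(DvhScoreError):
    """A metric-text string that does not match the scorecard grammar."""


class SchemaError(DvhScoreError):
    """A scorecard file violating the schema; message carries a location."""


class UnknownScorecard(DvhScoreError):
    """Request for a built-in scorecard name that does not exist."""


class MissingStructure(DvhScoreError):
    """A scorecard metric references a structure the plan cannot resolve."""


class NeedsDoseGrid(DvhScoreError):
    """A metric requiring the 3-D dose grid was evaluated on a DVH-only plan."""


class ConfigError(DvhScoreError):
    """Invalid phantom or tool configuration."""


class BundleError(DvhScoreError):
    """A plan bundle directory is missing or inconsistent."""


class EmptyBatch(DvhScoreError):
    """Batch scoring invoked with no plans or no scorecards."""
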