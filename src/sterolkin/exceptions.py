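"""Exception hierarchy for sterolkin."""


class SterolkinError(Exception):
    """Base class for all sterolkin errors."""


class DesignError(SterolkinError, ValueError):
    """Invalid storage-experiment design (e.g. validation condition not in the grid)."""


class GenerationError(SterolkinError, RuntimeError):
    """Synthetic-data generation failed (e.g. degradation surface non-positive)."""


class StateError(SterolkinError, RuntimeError):
    """Operation applied to a dataset in the wrong state (e.g. roles already assigned)."""


class DataError(SterolkinError, ValueError):
    """Dataset does not satisfy the preconditions of an operation."""


class RankDeficiencyError(SterolkinError, ValueError):
    """Design matrix is rank-deficient; the message names the offending column."""


class TrainingError(SterolkinError, RuntimeError):
    """Network training diverged or produced non-finite parameters."""
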