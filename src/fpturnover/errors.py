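"""Exception hierarchy shared across the pipeline stages.

The CLI maps these onto exit codes: configuration problems exit 2, data
problems exit 3, statistical degeneracies exit 4 under ``--strict``.
"""


class ConfigurationError(ValueError):
    """Invalid threshold/ROI/mask/pipeline configuration."""


class DataError(ValueError):
    """Input data violates a stage's contract (shape, emptiness, ordering)."""


class SynchronizationError(DataError):
    """Two camera streams that should be frame-synchronized are not."""


class NoDecayWindowError(DataError):
    """No peak-to-minimum segment exists in the time course."""


class DegenerateStatisticsWarning(UserWarning):
    """A statistical test hit a zero-variance / zero-residual edge case."""
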