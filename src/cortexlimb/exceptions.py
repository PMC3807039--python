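"""Exception hierarchy used across cortexlimb."""


class CortexLimbError(Exception):
    """Base class for all package errors."""


class InvalidInputError(CortexLimbError, ValueError):
    """Malformed or non-finite input data."""


class UnreachablePostureError(InvalidInputError):
    """Marker configuration outside the arm's reachable workspace."""


class SingularConfigurationError(InvalidInputError):
    """Joint configuration where the inverse kinematics degenerates."""


class DegenerateChannelError(InvalidInputError):
    """A reference channel has zero amplitude where a positive one is required."""


class FormatError(CortexLimbError, ValueError):
    """Unrecognized or corrupt container/file layout."""


class InvalidPriorError(InvalidInputError):
    """Prior hyperparameters outside their valid domain."""

class InvalidRoiError(InvalidInputError):
    """ROI indices outside the cortical source set."""


class NumericalError(CortexLimbError, RuntimeError):
    """Numerical failure (singular systems, NaNs in iterative traces)."""


class EstimationError(CortexLimbError, RuntimeError):
    """An estimator could not produce a usable result from the given data."""


class UndefinedMetricError(CortexLimbError, ValueError):
    """A metric is undefined for the given inputs (e.g. constant reference)."""


class ProtocolError(CortexLimbError, ValueError):
    """Evaluation protocol misuse (e.g. too few sets for cross-validation)."""


class ConfigurationError(CortexLimbError, ValueError):
    """Invalid simulation or run configuration."""


class ModelStateError(CortexLimbError, RuntimeError):
    """Operation requires a trained model."""


class TrainingError(CortexLimbError, RuntimeError):
    """Training diverged; carries the last good checkpoint when available."""

    def __init__(self, message, checkpoint=None):
        super().__init__(message)
        self.checkpoint = checkpoint
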