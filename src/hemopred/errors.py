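"""Exception hierarchy shared across the package."""


class HemopredError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(HemopredError, ValueError):
    """A physiological or numerical parameter violates its constraints."""


class SimulationFailureError(HemopredError, RuntimeError):
    """The integrator produced a non-finite state (numerical blow-up)."""


class PreconditionError(HemopredError, ValueError):
    """An operation was called on input that violates its contract."""


class FootDetectionError(HemopredError, ValueError):
    """The intersecting-tangents algorithm cannot locate a wave foot."""


class TransitError(HemopredError, ValueError):
    """Carotid-femoral transit time is non-positive; subject unusable."""


class ExtractionError(HemopredError, ValueError):
    """Feature/target extraction failed; the subject should be dropped."""


class FormatError(HemopredError, ValueError):
    """A serialised table does not conform to the expected schema."""


class ScenarioError(HemopredError, ValueError):
    """A regression scenario references columns absent from the dataset."""


class AlignmentError(HemopredError, ValueError):
    """Cross-validation runs are not aligned (dataset/folds differ)."""


class SweepError(HemopredError, ValueError):
    """A training-size fraction leaves too few test rows."""


class SingularDesignError(HemopredError, ValueError):
    """The OLS design matrix is rank deficient."""
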