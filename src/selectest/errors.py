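"""Exception hierarchy shared across the package."""


class SelectestError(Exception):
    """Base class for all package-specific errors."""


class InvalidTrialError(SelectestError):
    """Trial structure violates a hard precondition (e.g. fewer than 2 arms)."""


class NoStageTwoDataError(SelectestError):
    """An operation needing stage-2 data was asked for a rank without any."""


class InsufficientDFError(SelectestError):
    """Degrees of freedom are zero or negative (N <= k, or pooled df < 1)."""


class DegenerateDataError(SelectestError):
    """All observed values coincide; scale estimates are identically zero."""


class DegenerateIntervalError(SelectestError):
    """The conditioning interval is so extreme that the closed-form kernel
    underflows; callers should fall back to quadrature."""


class WrongSpecialCaseError(SelectestError):
    """The equal-sample-size single-observation estimator was applied to data
    that does not satisfy its restrictions."""


class NonConvergenceError(SelectestError):
    """An iterative solver exhausted its search cap without a solution."""


class TieWarning(UserWarning):
    """Stage-1 ranking statistics were exactly tied; ties broken by arm order."""


class DegenerateIntervalWarning(UserWarning):
    """Quadrature interval shorter than resolvable; midpoint returned."""
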