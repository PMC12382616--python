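"""Exception hierarchy for rewardmap.

All package-specific errors derive from :class:`RewardmapError` so callers
can catch pipeline failures with a single except clause while still
distinguishing configuration problems from numerical degeneracies.
"""


class RewardmapError(Exception):
    """Base class for all rewardmap errors."""


class InvalidDesignError(RewardmapError, ValueError):
    """Task-design specification is inconsistent (e.g. trial counts)."""


class InvalidInputError(RewardmapError, ValueError):
    """Inputs violate a precondition (ordering, lengths, grids)."""


class InvalidParameterError(RewardmapError, ValueError):
    """A model parameter is outside its admissible range."""


class InvalidSpecError(RewardmapError, ValueError):
    """A phantom specification is internally inconsistent."""


class InvalidCouplingError(RewardmapError, ValueError):
    """Requested covariate-amplitude coupling is unattainable."""


class DegenerateInputError(RewardmapError, ValueError):
    """Data carry no usable variance for the requested operation."""


class DegenerateModelError(RewardmapError, ValueError):
    """Model has no residual degrees of freedom."""


class InvalidContrastError(RewardmapError, ValueError):
    """Contrast vector is incompatible with the fitted design."""


class ConvergenceError(RewardmapError, RuntimeError):
    """Iterative algorithm failed to converge within its iteration budget.

    Carries ``diagnostics`` (dict) with the iteration count and the last
    observed update size so callers can adjust penalties or budgets.
    """

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}
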