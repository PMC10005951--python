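"""Exception hierarchy for hubspin.

All user-facing errors derive from :class:`HubspinError` so callers (and the
CLI) can catch one base class.
"""


class HubspinError(Exception):
    """Base class for all hubspin errors."""


class InvalidArgumentError(HubspinError, ValueError):
    """An argument violates a documented precondition."""


class AlignmentError(HubspinError, ValueError):
    """Two inputs that must share labels / row order do not."""


class ShapeError(HubspinError, ValueError):
    """Dimension mismatch between inputs."""


class DegenerateDesignError(HubspinError, ValueError):
    """A categorical model term has fewer than two observed levels."""


class CollinearityError(HubspinError, ValueError):
    """The design matrix is rank deficient.

    Carries the names of the offending columns in ``columns``.
    """

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; offending columns: "
            + ", ".join(self.columns)
        )


class InsufficientDataError(HubspinError, ValueError):
    """Too few residual degrees of freedom to fit the model."""


class DegenerateMapError(HubspinError, ValueError):
    """A map that must have nonzero variance is constant."""


class DegenerateTargetError(HubspinError, ValueError):
    """A prediction target that must vary is constant."""


class DegeneratePRSError(HubspinError, ValueError):
    """The polygenic-score construction has no signal and no noise."""


class ConvergenceError(HubspinError, RuntimeError):
    """An iterative search failed to reach its target."""
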