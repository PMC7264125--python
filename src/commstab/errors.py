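"""Exception hierarchy shared across the package."""


class CommstabError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(CommstabError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedStatisticError(CommstabError, ValueError):
    """The requested statistic is undefined for this input (e.g. zero mean)."""


class DegenerateCommunityError(CommstabError, ValueError):
    """A stability component diverges (-log 0); carries which one.

    Callers typically exclude the community from downstream regressions.
    """

    def __init__(self, component: str, site_id=None):
        self.component = component
        self.site_id = site_id
        where = f" at site {site_id!r}" if site_id is not None else ""
        super().__init__(
            f"degenerate community{where}: {component} is zero, its negative "
            f"log is unbounded"
        )


class DegenerateInputError(CommstabError, ValueError):
    """Input has no usable variation (e.g. a constant column)."""


class DegenerateRegressionError(CommstabError, ValueError):
    """A regression cannot be fit (zero predictor variance)."""


class MissingTaxonError(CommstabError, KeyError):
    """Community references taxa absent from the phylogeny."""

    def __init__(self, taxa):
        self.taxa = sorted(taxa)
        super().__init__(f"taxa missing from the tree: {', '.join(self.taxa)}")


class CollinearityError(CommstabError, ValueError):
    """Singular design matrix."""


class NumericalError(CommstabError, ArithmeticError):
    """Non-convergence or non-finite intermediate values."""


class PipelineError(CommstabError, RuntimeError):
    """A pipeline stage failed; message names the stage and cause."""
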