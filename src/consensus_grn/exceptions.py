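"""Exception hierarchy for the consensus-GRN pipeline.

Every error raised by the library derives from :class:`GrnError`, so callers
(and the CLI) can catch one type. Subclasses distinguish input-contract
violations from numerical degeneracies.
"""


class GrnError(Exception):
    """Base class for all consensus-GRN errors."""


class ValidationError(GrnError):
    """Malformed input data: duplicate ids, non-numeric cells, missing values."""


class DimensionError(GrnError):
    """Input has the wrong shape (e.g. fewer than 4 conditions)."""


class DegenerateGeneError(GrnError):
    """A gene row is constant, so it cannot be standardized or correlated."""


class ParameterError(GrnError):
    """A tuning parameter violates its preconditions (k, v, lambda, B, alpha...)."""


class ContractError(GrnError):
    """An operation was called on data violating its contract (e.g. unstandardized)."""


class SingularityError(GrnError):
    """A linear system is singular (ridge with lambda=0 on a rank-deficient design)."""


class DegenerateNullError(GrnError):
    """The empirical null cannot be fitted (all t-statistics identical/zero)."""
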