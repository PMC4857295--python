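"""Exception hierarchy for nntplan.

All library errors derive from :class:`NNTPlanError`, so callers (and the
CLI) can catch one base class.  Errors that signal invalid numeric input
also derive from :class:`ValueError` for idiomatic handling.
"""

from __future__ import annotations


class NNTPlanError(Exception):
    """Base class for all nntplan errors."""


class DomainError(NNTPlanError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class InconsistentRangeError(DomainError):
    """The elicited NNT bounds are ordered the wrong way round.

    Raised when ``nnt_lower >= nnt_upper`` — the elicited predictive values
    imply a discomfort range that is empty, so the elicitation must be
    revisited.
    """


class InfeasibleError(NNTPlanError, ValueError):
    """Requested predictive values cannot arise at the given prevalence.

    The inverse (contra-Bayes) mapping has a solution in [0, 1]^2 only when
    a positive result raises the prior odds and a negative result lowers
    them: ``PPO > Odds > 1/NPO``.  ``failed_side`` records which inequality
    broke ("positive", "negative" or "both").
    """

    def __init__(self, message: str, failed_side: str | None = None):
        super().__init__(message)
        self.failed_side = failed_side


class DegenerateTestError(NNTPlanError, ValueError):
    """A sensitivity/specificity combination leaves a predictive value undefined."""


class SchemaError(NNTPlanError, ValueError):
    """A scaffold config file violates the documented schema."""
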