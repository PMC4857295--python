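"""Prospective and retrospective validation-study summaries.

A *prospective* study recruits a cohort, applies the test, and follows
both arms, estimating PPV and NPV directly as binomial proportions.  A
*retrospective* (case-control) study samples known BestToAct cases and
BestToWait controls and estimates sensitivity and specificity; recovering
predictive values then needs the prevalence.

This module turns anticipated results into the interval estimates a
design team inspects before committing to sample sizes:

* exact (Clopper-Pearson) two-sided confidence intervals for binomial
  proportions, transformed to the NNT scale by the monotone maps
  NNT_Pos = 1/PPV and NNT_Neg = 1/(1-NPV);
* Monte-Carlo Bayes predictive intervals for NNT_Pos and NNT_Neg under
  independent Jeffreys (Beta(1/2, 1/2)) priors on SN and SP;
* a deterministic search for the smallest group sizes whose anticipated
  confidence intervals clear a discomfort range.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .bayes_maps import Prevalence, TestCharacteristics, contra_bayes, forward_arrays
from .exceptions import DomainError, InfeasibleError
from .nnt_core import (
    DiscomfortRange,
    NNTPair,
    PredictiveValues,
    is_clinically_useful,
    npv_from_nnt_neg,
    ppv_from_nnt_pos,
    required_predictive_values,
    round_half_up,
)

logger = logging.getLogger("nntplan")

__all__ = [
    "BinomialOutcome",
    "IntervalEstimate",
    "ProspectiveDesign",
    "RetrospectiveDesign",
    "McSettings",
    "ProspectiveReport",
    "RetrospectiveReport",
    "MinimumSampleSizes",
    "exact_binomial_ci",
    "nnt_interval_from_pv_interval",
    "anticipated_prospective_counts",
    "prospective_summary",
    "bayes_predictive_nnt_intervals",
    "retrospective_summary",
    "minimum_n_search",
]

EXACT_BINOMIAL = "exact-binomial"
BAYES_PREDICTIVE = "bayes-predictive"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class BinomialOutcome:
    """Successes out of trials, e.g. anticipated true positives among cases."""

    successes: int
    trials: int

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise DomainError(f"trials must be >= 1, got {self.trials!r}")
        if not 0 <= self.successes <= self.trials:
            raise DomainError(
                f"successes must lie in [0, trials], got {self.successes!r}/{self.trials!r}"
            )

    @property
    def proportion(self) -> float:
        return self.successes / self.trials


@dataclass(frozen=True)
class IntervalEstimate:
    """A two-sided interval with its level and the method that produced it."""

    lower: float
    upper: float
    level: float
    method: str

    def __post_init__(self) -> None:
        if not self.lower <= self.upper:
            raise DomainError(f"interval bounds out of order: ({self.lower!r}, {self.upper!r})")

    @property
    def width(self) -> float:
        return self.upper - self.lower


@dataclass(frozen=True)
class ProspectiveDesign:
    """A cohort of ``n_total`` patients splitting into test-positive and -negative arms.

    ``target`` holds the hoped-for NNT values in the two arms; anticipated
    counts are derived from it by :func:`anticipated_prospective_counts`.
    """

    n_total: int
    positive_fraction: float
    target: NNTPair
    followup_note: str = ""

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise DomainError(f"n_total must be >= 2, got {self.n_total!r}")
        if not 0.0 < self.positive_fraction < 1.0:
            raise DomainError(
                f"positive_fraction must lie strictly in (0, 1), got {self.positive_fraction!r}"
            )


@dataclass(frozen=True)
class RetrospectiveDesign:
    """Case-control design with anticipated SN/SP outcomes and a prevalence."""

    n_cases: int
    n_controls: int
    anticipated_sn: BinomialOutcome
    anticipated_sp: BinomialOutcome
    prevalence: Prevalence

    def __post_init__(self) -> None:
        if self.anticipated_sn.trials != self.n_cases:
            raise DomainError(
                f"anticipated_sn has {self.anticipated_sn.trials} trials "
                f"but n_cases = {self.n_cases}"
            )
        if self.anticipated_sp.trials != self.n_controls:
            raise DomainError(
                f"anticipated_sp has {self.anticipated_sp.trials} trials "
                f"but n_controls = {self.n_controls}"
            )


@dataclass(frozen=True)
class McSettings:
    """Monte-Carlo settings; the default draw count targets sub-second runs."""

    n_draws: int = 100_000
    seed: int = 1234

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise DomainError(f"n_draws must be >= 1, got {self.n_draws!r}")


# --------------------------------------------------------------------------
# Exact confidence intervals and NNT transforms
# --------------------------------------------------------------------------

def exact_binomial_ci(o: BinomialOutcome, level: float = 0.95) -> IntervalEstimate:
    """Two-sided exact (Clopper-Pearson) confidence interval.

    The lower bound is exactly 0 when ``successes == 0`` and the upper
    bound exactly 1 when ``successes == trials``.
    """
    if not 0.0 < level < 1.0:
        raise DomainError(f"confidence level must lie strictly in (0, 1), got {level!r}")
    ci = stats.binomtest(o.successes, o.trials).proportion_ci(
        confidence_level=level, method="exact"
    )
    return IntervalEstimate(lower=float(ci.low), upper=float(ci.high),
                            level=level, method=EXACT_BINOMIAL)


def nnt_interval_from_pv_interval(iv: IntervalEstimate, side: str) -> IntervalEstimate:
    """Map a predictive-value interval onto the NNT scale.

    ``side="pos"``: PPV interval (l, u) -> NNT_Pos interval (1/u, 1/l)
    (order-reversing reciprocal).  ``side="neg"``: NPV interval (l, u) ->
    NNT_Neg interval (1/(1-l), 1/(1-u)), upper infinite at NPV = 1.
    """
    if side == "pos":
        if iv.lower <= 0.0:
            raise DomainError(
                "cannot take the reciprocal of a PPV interval reaching 0 "
                f"(lower bound {iv.lower!r})"
            )
        return IntervalEstimate(lower=1.0 / iv.upper, upper=1.0 / iv.lower,
                                level=iv.level, method=iv.method)
    if side == "neg":
        lower = 1.0 / (1.0 - iv.lower) if iv.lower < 1.0 else math.inf
        upper = 1.0 / (1.0 - iv.upper) if iv.upper < 1.0 else math.inf
        return IntervalEstimate(lower=lower, upper=upper, level=iv.level, method=iv.method)
    raise DomainError(f"side must be 'pos' or 'neg', got {side!r}")


def _round_half_away(x: float) -> int:
    """Nearest integer, ties away from zero (via the display guard)."""
    return int(round_half_up(x, 0))


def anticipated_prospective_counts(
    d: ProspectiveDesign,
) -> tuple[BinomialOutcome, BinomialOutcome]:
    """Counts expected if the study matches the target NNT values exactly.

    The positive arm contributes ``round(n_pos / nnt_pos)`` true positives
    among ``n_pos``; the negative arm contributes
    ``n_neg - round(n_neg / nnt_neg)`` true negatives among ``n_neg``
    (the NPV numerator).  Rounding is to the nearest integer, ties away
    from zero.
    """
    n_pos = _round_half_away(d.n_total * d.positive_fraction)
    n_neg = d.n_total - n_pos
    if n_pos < 1 or n_neg < 1:
        raise DomainError(
            f"positive_fraction {d.positive_fraction!r} leaves an empty arm "
            f"for n_total = {d.n_total}"
        )
    tp = _round_half_away(n_pos / d.target.nnt_pos)
    fn = 0 if math.isinf(d.target.nnt_neg) else _round_half_away(n_neg / d.target.nnt_neg)
    tn = n_neg - fn
    if not 0 <= tp <= n_pos or not 0 <= tn <= n_neg:
        raise DomainError(
            f"target {d.target!r} implies counts outside the group sizes "
            f"({tp}/{n_pos} positives, {tn}/{n_neg} negatives)"
        )
    return BinomialOutcome(tp, n_pos), BinomialOutcome(tn, n_neg)


# --------------------------------------------------------------------------
# Prospective summary
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ProspectiveReport:
    """Anticipated precision of a prospective design, on both scales."""

    design: ProspectiveDesign
    level: float
    positives: BinomialOutcome
    negatives: BinomialOutcome
    ppv_ci: IntervalEstimate
    npv_ci: IntervalEstimate
    nnt_pos_ci: IntervalEstimate
    nnt_neg_ci: IntervalEstimate
    discomfort_range: DiscomfortRange | None = None
    clears_positive: bool | None = None
    clears_negative: bool | None = None


def prospective_summary(
    d: ProspectiveDesign,
    level: float = 0.95,
    discomfort_range: DiscomfortRange | None = None,
) -> ProspectiveReport:
    """Anticipated PPV/NPV confidence intervals and their NNT transforms.

    When a discomfort range is supplied the report flags whether the
    anticipated NNT intervals clear it entirely (upper NNT_Pos bound below
    ``nnt_lower``; lower NNT_Neg bound above ``nnt_upper``).
    """
    positives, negatives = anticipated_prospective_counts(d)
    ppv_ci = exact_binomial_ci(positives, level)
    npv_ci = exact_binomial_ci(negatives, level)
    nnt_pos_ci = nnt_interval_from_pv_interval(ppv_ci, "pos")
    nnt_neg_ci = nnt_interval_from_pv_interval(npv_ci, "neg")
    clears_pos = clears_neg = None
    if discomfort_range is not None:
        clears_pos = nnt_pos_ci.upper < discomfort_range.nnt_lower
        clears_neg = nnt_neg_ci.lower > discomfort_range.nnt_upper
    return ProspectiveReport(
        design=d, level=level, positives=positives, negatives=negatives,
        ppv_ci=ppv_ci, npv_ci=npv_ci, nnt_pos_ci=nnt_pos_ci, nnt_neg_ci=nnt_neg_ci,
        discomfort_range=discomfort_range,
        clears_positive=clears_pos, clears_negative=clears_neg,
    )


# --------------------------------------------------------------------------
# Bayes predictive intervals (retrospective design)
# --------------------------------------------------------------------------

def bayes_predictive_nnt_intervals(
    d: RetrospectiveDesign,
    level: float = 0.95,
    mc: McSettings = McSettings(),
) -> tuple[IntervalEstimate, IntervalEstimate]:
    """Equal-tailed Bayes predictive intervals for NNT_Pos and NNT_Neg.

    SN and SP are drawn independently from their Jeffreys posteriors
    ``Beta(x + 1/2, n - x + 1/2)`` given the anticipated counts; each draw
    is pushed through forward Bayes at the design prevalence and onto the
    NNT scale.  Bit-reproducible for a fixed seed and draw count.
    """
    if not 0.0 < level < 1.0:
        raise DomainError(f"level must lie strictly in (0, 1), got {level!r}")
    if mc.n_draws < 10_000:
        warnings.warn(
            f"n_draws = {mc.n_draws} is small for {level:.0%} predictive intervals; "
            "consider >= 10,000",
            stacklevel=2,
        )
    logger.info(
        "bayes_predictive_nnt_intervals: level=%g seed=%d draws=%d",
        level, mc.seed, mc.n_draws,
    )
    rng = np.random.default_rng(mc.seed)
    x_sn, n_sn = d.anticipated_sn.successes, d.anticipated_sn.trials
    x_sp, n_sp = d.anticipated_sp.successes, d.anticipated_sp.trials
    sn = rng.beta(x_sn + 0.5, n_sn - x_sn + 0.5, mc.n_draws)
    sp = rng.beta(x_sp + 0.5, n_sp - x_sp + 0.5, mc.n_draws)
    ppv, npv = forward_arrays(sn, sp, d.prevalence.value)
    nnt_pos = 1.0 / ppv
    with np.errstate(divide="ignore"):
        nnt_neg = 1.0 / (1.0 - npv)
    alpha = (1.0 - level) / 2.0
    qp = np.quantile(nnt_pos, [alpha, 1.0 - alpha])
    qn = np.quantile(nnt_neg, [alpha, 1.0 - alpha])
    return (
        IntervalEstimate(float(qp[0]), float(qp[1]), level, BAYES_PREDICTIVE),
        IntervalEstimate(float(qn[0]), float(qn[1]), level, BAYES_PREDICTIVE),
    )


@dataclass(frozen=True)
class RetrospectiveReport:
    """Anticipated precision of a case-control design, plus requirements."""

    design: RetrospectiveDesign
    level: float
    mc: McSettings
    sn_ci: IntervalEstimate
    sp_ci: IntervalEstimate
    nnt_pos_pi: IntervalEstimate
    nnt_neg_pi: IntervalEstimate
    discomfort_range: DiscomfortRange | None = None
    required: TestCharacteristics | None = None
    meets_required_sn: bool | None = None
    meets_required_sp: bool | None = None


def retrospective_summary(
    d: RetrospectiveDesign,
    level: float = 0.95,
    mc: McSettings = McSettings(),
    discomfort_range: DiscomfortRange | None = None,
) -> RetrospectiveReport:
    """Exact SN/SP intervals, predictive NNT intervals, and required SN/SP.

    With a discomfort range the required sensitivity and specificity are
    obtained by contra-Bayes from the range's predictive-value thresholds
    at the design prevalence, and the anticipated point estimates are
    flagged against them.
    """
    sn_ci = exact_binomial_ci(d.anticipated_sn, level)
    sp_ci = exact_binomial_ci(d.anticipated_sp, level)
    pi_pos, pi_neg = bayes_predictive_nnt_intervals(d, level, mc)
    required = meets_sn = meets_sp = None
    if discomfort_range is not None:
        required = contra_bayes(required_predictive_values(discomfort_range), d.prevalence)
        meets_sn = d.anticipated_sn.proportion > required.sensitivity
        meets_sp = d.anticipated_sp.proportion > required.specificity
    return RetrospectiveReport(
        design=d, level=level, mc=mc, sn_ci=sn_ci, sp_ci=sp_ci,
        nnt_pos_pi=pi_pos, nnt_neg_pi=pi_neg,
        discomfort_range=discomfort_range, required=required,
        meets_required_sn=meets_sn, meets_required_sp=meets_sp,
    )


# --------------------------------------------------------------------------
# Minimum sample-size search
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class MinimumSampleSizes:
    """Result of :func:`minimum_n_search`: the two group sizes and the shape."""

    shape: str
    n_first: int   # positives (prospective) / cases (retrospective)
    n_second: int  # negatives (prospective) / controls (retrospective)


def _smallest_clearing_n(p_hat: float, threshold: float, level: float, n_max: int) -> int:
    """Smallest n whose Clopper-Pearson lower bound at counts round(n*p_hat)
    strictly exceeds ``threshold``.

    Bracket by doubling, then scan linearly from 2 — deterministic and
    robust to the non-monotonicity induced by count rounding.
    """
    def clears(n: int) -> bool:
        x = _round_half_away(n * p_hat)
        x = min(max(x, 0), n)
        return exact_binomial_ci(BinomialOutcome(x, n), level).lower > threshold

    n = 2
    while n <= n_max and not clears(n):
        n *= 2
    if n > n_max:
        raise InfeasibleError(
            f"no n <= {n_max} gives a {level:.0%} lower confidence bound above "
            f"{threshold:.6g} at anticipated proportion {p_hat:.6g}"
        )
    bracket = n
    for m in range(2, bracket + 1):
        if clears(m):
            return m
    return bracket


def minimum_n_search(
    target: NNTPair,
    dr: DiscomfortRange,
    shape: str = "prospective",
    level: float = 0.95,
    prevalence: Prevalence | None = None,
    n_max: int = 1_000_000,
) -> MinimumSampleSizes:
    """Smallest group sizes whose anticipated intervals clear the range.

    ``shape="prospective"`` searches the test-positive and test-negative
    group sizes so that the anticipated NNT_Pos interval lies entirely
    below ``nnt_lower`` and the NNT_Neg interval entirely above
    ``nnt_upper``.  ``shape="retrospective"`` (requires ``prevalence``)
    searches cases and controls so the anticipated SN and SP lower
    confidence bounds exceed the contra-Bayes requirements.

    The target must satisfy the usefulness criterion strictly; a target on
    the boundary of the range is reported as infeasible.
    """
    verdict = is_clinically_useful(target, dr)
    if not verdict:
        raise InfeasibleError("target NNT pair cannot clear the range: " + verdict.message)

    if shape == "prospective":
        ppv_hat = ppv_from_nnt_pos(target.nnt_pos)
        npv_hat = npv_from_nnt_neg(target.nnt_neg)
        thr = required_predictive_values(dr)
        n_pos = _smallest_clearing_n(ppv_hat, thr.ppv, level, n_max)
        n_neg = _smallest_clearing_n(npv_hat, thr.npv, level, n_max)
        return MinimumSampleSizes(shape=shape, n_first=n_pos, n_second=n_neg)

    if shape == "retrospective":
        if prevalence is None:
            raise DomainError("retrospective shape requires a prevalence")
        anticipated_pv = PredictiveValues(
            ppv=ppv_from_nnt_pos(target.nnt_pos),
            npv=npv_from_nnt_neg(target.nnt_neg),
        )
        anticipated_tc = contra_bayes(anticipated_pv, prevalence)
        required_tc = contra_bayes(required_predictive_values(dr), prevalence)
        n_cases = _smallest_clearing_n(
            anticipated_tc.sensitivity, required_tc.sensitivity, level, n_max
        )
        n_controls = _smallest_clearing_n(
            anticipated_tc.specificity, required_tc.specificity, level, n_max
        )
        return MinimumSampleSizes(shape=shape, n_first=n_cases, n_second=n_controls)

    raise DomainError(f"shape must be 'prospective' or 'retrospective', got {shape!r}")
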