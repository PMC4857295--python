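"""Number-needed-to-treat scale and its link to predictive values.

The number needed to treat (NNT) is the expected number of patients one
must treat for one to benefit.  Restricted to the subgroups defined by a
binary biomarker test it splits into ``NNT_Pos`` (test-positive patients)
and ``NNT_Neg`` (test-negative patients), which map one-to-one onto the
test's predictive values::

    PPV = 1 / NNT_Pos          NPV = 1 - 1 / NNT_Neg

A clinical team elicits a *discomfort range* ``(NNT_Lower, NNT_Upper)``:
for observed NNT inside this interval neither treating everybody nor
withholding treatment from everybody feels acceptable.  A test is
clinically useful when it pushes both subgroups out of the range,

    NNT_Pos < NNT_Lower  and  NNT_Neg > NNT_Upper,

which translates into minimum predictive-value requirements
``PPV > 1/NNT_Lower`` and ``NPV > 1 - 1/NNT_Upper``.

All stored values are exact; rounding happens only in the display helpers
(:func:`round_half_up`, :func:`format_percent`, :func:`format_nnt`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

from .exceptions import DomainError, InconsistentRangeError

__all__ = [
    "DiscomfortRange",
    "NNTPair",
    "PredictiveValues",
    "UsefulnessReport",
    "ppv_from_nnt_pos",
    "npv_from_nnt_neg",
    "nnt_pair_from_predictive_values",
    "required_predictive_values",
    "is_clinically_useful",
    "validate_discomfort_range",
    "round_half_up",
    "format_percent",
    "format_nnt",
]


# --------------------------------------------------------------------------
# Display rounding
#
# Convention: half-way cases round away from zero (so 1/0.80 = 1.25 prints
# as 1.3), with a 9-decimal guard rounding first so that values such as
# 23/4 computed in floating point as 5.749999999999997 still print as 5.8.
# Stored values are never rounded.
# --------------------------------------------------------------------------

def round_half_up(value: float, ndigits: int = 0) -> float:
    """Round with ties away from zero, after a 9-decimal float-fuzz guard."""
    guarded = round(float(value), 9)
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(guarded)).quantize(quantum, rounding=ROUND_HALF_UP))


def format_percent(p: float, decimals: int = 0) -> str:
    """Format a probability as a percentage string, e.g. 0.5 -> '50%'."""
    return f"{round_half_up(100.0 * p, decimals):.{decimals}f}%"


def format_nnt(x: float) -> str:
    """Format an NNT: 'Inf' if infinite, 1 decimal up to 100, 3 s.f. above."""
    if math.isinf(x):
        return "Inf"
    if x <= 100:
        return f"{round_half_up(x, 1):.1f}"
    ndigits = 2 - math.floor(math.log10(abs(x)))
    return f"{round_half_up(x, ndigits):.0f}"


# --------------------------------------------------------------------------
# Domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscomfortRange:
    """Elicited ethical bounds on the NNT scale, ``1 <= nnt_lower < nnt_upper``.

    For NNT below ``nnt_lower`` treating everyone is comfortable; above
    ``nnt_upper`` waiting is comfortable; in between, neither.
    """

    nnt_lower: float
    nnt_upper: float

    def __post_init__(self) -> None:
        for name, v in (("nnt_lower", self.nnt_lower), ("nnt_upper", self.nnt_upper)):
            if not math.isfinite(v):
                raise DomainError(f"{name} must be finite, got {v!r}")
            if v < 1:
                raise DomainError(f"{name} must be >= 1 (an expected count), got {v!r}")
        if self.nnt_lower >= self.nnt_upper:
            raise InconsistentRangeError(
                f"inconsistent range: nnt_lower = {self.nnt_lower!r} must be "
                f"strictly smaller than nnt_upper = {self.nnt_upper!r}; the "
                "elicited values do not describe a discomfort range and the "
                "elicitation should be revisited"
            )


@dataclass(frozen=True)
class NNTPair:
    """NNT in the test-positive and test-negative subgroups.

    ``nnt_neg`` may be ``math.inf`` (a test whose negatives never benefit
    from treatment, NPV = 1); it is displayed as ``"Inf"``.
    """

    nnt_pos: float
    nnt_neg: float

    def __post_init__(self) -> None:
        if math.isnan(self.nnt_pos) or not math.isfinite(self.nnt_pos):
            raise DomainError(f"nnt_pos must be finite, got {self.nnt_pos!r}")
        if self.nnt_pos < 1:
            raise DomainError(f"nnt_pos must be >= 1, got {self.nnt_pos!r}")
        if math.isnan(self.nnt_neg) or self.nnt_neg <= 1:
            raise DomainError(f"nnt_neg must be > 1 (or infinite), got {self.nnt_neg!r}")


@dataclass(frozen=True)
class PredictiveValues:
    """Positive and negative predictive values, both in (0, 1]."""

    ppv: float
    npv: float

    def __post_init__(self) -> None:
        if not 0.0 < self.ppv <= 1.0:
            raise DomainError(f"ppv must lie in (0, 1], got {self.ppv!r}")
        if not 0.0 < self.npv <= 1.0:
            raise DomainError(f"npv must lie in (0, 1], got {self.npv!r}")

    @property
    def ppo(self) -> float:
        """Positive predictive odds PPV/(1-PPV); infinite at PPV = 1."""
        return math.inf if self.ppv == 1.0 else self.ppv / (1.0 - self.ppv)

    @property
    def npo(self) -> float:
        """Negative predictive odds NPV/(1-NPV); infinite at NPV = 1."""
        return math.inf if self.npv == 1.0 else self.npv / (1.0 - self.npv)


@dataclass(frozen=True)
class UsefulnessReport:
    """Outcome of the clinical-usefulness check, with a per-side verdict."""

    useful: bool
    positive_ok: bool
    negative_ok: bool
    message: str

    def __bool__(self) -> bool:
        return self.useful


# --------------------------------------------------------------------------
# Operations
# --------------------------------------------------------------------------

def ppv_from_nnt_pos(nnt_pos: float) -> float:
    """PPV implied by the NNT among test positives: ``1 / nnt_pos``."""
    if math.isnan(nnt_pos) or not math.isfinite(nnt_pos):
        raise DomainError(f"nnt_pos must be finite, got {nnt_pos!r}")
    if nnt_pos < 1:
        raise DomainError(f"nnt_pos must be >= 1, got {nnt_pos!r}")
    return 1.0 / nnt_pos


def npv_from_nnt_neg(nnt_neg: float) -> float:
    """NPV implied by the NNT among test negatives: ``1 - 1/nnt_neg``.

    An infinite ``nnt_neg`` (no benefit forgone among negatives) gives
    exactly 1.
    """
    if math.isnan(nnt_neg) or nnt_neg <= 1:
        raise DomainError(f"nnt_neg must be > 1 (or infinite), got {nnt_neg!r}")
    if math.isinf(nnt_neg):
        return 1.0
    return 1.0 - 1.0 / nnt_neg


def nnt_pair_from_predictive_values(pv: PredictiveValues) -> NNTPair:
    """Invert the NNT/predictive-value mappings.

    ``nnt_pos = 1/PPV`` and ``nnt_neg = 1/(1-NPV)``, infinite when NPV = 1.
    """
    nnt_pos = 1.0 / pv.ppv
    nnt_neg = math.inf if pv.npv == 1.0 else 1.0 / (1.0 - pv.npv)
    return NNTPair(nnt_pos=nnt_pos, nnt_neg=nnt_neg)


def required_predictive_values(dr: DiscomfortRange) -> PredictiveValues:
    """Minimum predictive values a useful test must *strictly* exceed.

    ``PPV > 1/NNT_Lower`` and ``NPV > 1 - 1/NNT_Upper``.  The returned
    values are the strict lower thresholds themselves.
    """
    return PredictiveValues(
        ppv=1.0 / dr.nnt_lower,
        npv=1.0 - 1.0 / dr.nnt_upper,
    )


def is_clinically_useful(nnt: NNTPair, dr: DiscomfortRange) -> UsefulnessReport:
    """Check ``NNT_Pos < NNT_Lower < NNT_Upper < NNT_Neg`` (strictly).

    Returns a truthy/falsy report naming the failing side(s).
    """
    positive_ok = nnt.nnt_pos < dr.nnt_lower
    negative_ok = nnt.nnt_neg > dr.nnt_upper
    if positive_ok and negative_ok:
        msg = (
            f"useful: NNT_Pos = {format_nnt(nnt.nnt_pos)} < {format_nnt(dr.nnt_lower)}"
            f" and NNT_Neg = {format_nnt(nnt.nnt_neg)} > {format_nnt(dr.nnt_upper)}"
        )
    else:
        failures = []
        if not positive_ok:
            failures.append(
                f"positive group: NNT_Pos = {format_nnt(nnt.nnt_pos)} is not "
                f"below NNT_Lower = {format_nnt(dr.nnt_lower)}"
            )
        if not negative_ok:
            failures.append(
                f"negative group: NNT_Neg = {format_nnt(nnt.nnt_neg)} is not "
                f"above NNT_Upper = {format_nnt(dr.nnt_upper)}"
            )
        msg = "not useful — " + "; ".join(failures)
    return UsefulnessReport(
        useful=positive_ok and negative_ok,
        positive_ok=positive_ok,
        negative_ok=negative_ok,
        message=msg,
    )


def validate_discomfort_range(nnt_lower: float, nnt_upper: float) -> DiscomfortRange:
    """Construct a :class:`DiscomfortRange`, diagnosing inconsistent elicitations.

    Elicited predictive values that look innocuous can imply reversed
    bounds (e.g. PPV 15% and NPV 70% give 6.7 and 3.3); the raised
    :class:`InconsistentRangeError` mirrors that diagnosis.
    """
    return DiscomfortRange(nnt_lower=float(nnt_lower), nnt_upper=float(nnt_upper))
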