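"""Forward Bayes and its closed-form inversion ("contra-Bayes").

Forward direction: sensitivity SN, specificity SP and the prevalence
p = Pr(BestToAct) give the predictive values

    PPV = SN p / (SN p + (1-SP)(1-p))
    NPV = SP (1-p) / (SP (1-p) + (1-SN) p)

Inverse direction: writing Odds = p/(1-p), PPO = PPV/(1-PPV) and
NPO = NPV/(1-NPV), the unique (SN, SP) reproducing given predictive
values at a given prevalence is

    SP = (PPO - Odds) / (PPO - NPO^-1)
    SN = (NPO - Odds^-1) / (NPO - PPO^-1)

valid in [0, 1]^2 exactly on the *feasible* set where the test moves the
prior odds in the expected directions: PPO > Odds > NPO^-1 (strict).
Internally the inverse is computed from the reciprocal odds
(1-PPV)/PPV and (1-NPV)/NPV, which stay finite as PPV or NPV -> 1, so
perfect predictive values are handled without propagating infinities.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateTestError, DomainError, InfeasibleError
from .nnt_core import PredictiveValues

__all__ = [
    "TestCharacteristics",
    "Prevalence",
    "FeasibilityReport",
    "bayes_forward",
    "contra_bayes",
    "check_feasible",
    "forward_arrays",
    "contra_arrays",
]


@dataclass(frozen=True)
class TestCharacteristics:
    """Sensitivity and specificity of a binary test, both in [0, 1]."""

    __test__ = False  # domain type, despite the pytest-like name

    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.sensitivity <= 1.0:
            raise DomainError(f"sensitivity must lie in [0, 1], got {self.sensitivity!r}")
        if not 0.0 <= self.specificity <= 1.0:
            raise DomainError(f"specificity must lie in [0, 1], got {self.specificity!r}")


@dataclass(frozen=True)
class Prevalence:
    """Prior probability Pr(BestToAct), strictly inside (0, 1)."""

    value: float

    def __post_init__(self) -> None:
        if not 0.0 < self.value < 1.0:
            raise DomainError(f"prevalence must lie strictly in (0, 1), got {self.value!r}")

    @property
    def odds(self) -> float:
        """Prior odds Pr(BestToAct)/Pr(BestToWait)."""
        return self.value / (1.0 - self.value)


@dataclass(frozen=True)
class FeasibilityReport:
    """Margins of the feasibility condition ``PPO > Odds > NPO^-1``.

    ``margin_positive = PPO - Odds`` and ``margin_negative = Odds - NPO^-1``;
    the predictive values are attainable at the prevalence iff both are
    strictly positive.
    """

    feasible: bool
    margin_positive: float
    margin_negative: float

    def __bool__(self) -> bool:
        return self.feasible

    @property
    def failed_side(self) -> str | None:
        if self.feasible:
            return None
        pos_bad = not self.margin_positive > 0
        neg_bad = not self.margin_negative > 0
        return "both" if (pos_bad and neg_bad) else ("positive" if pos_bad else "negative")


# --------------------------------------------------------------------------
# Array kernels (shared with the region module; no validation, no checks)
# --------------------------------------------------------------------------

def forward_arrays(sn, sp, p):
    """Vectorised forward Bayes; returns ``(ppv, npv)`` ndarrays."""
    sn = np.asarray(sn, dtype=float)
    sp = np.asarray(sp, dtype=float)
    p = np.asarray(p, dtype=float)
    ppv = sn * p / (sn * p + (1.0 - sp) * (1.0 - p))
    npv = sp * (1.0 - p) / (sp * (1.0 - p) + (1.0 - sn) * p)
    return ppv, npv


def contra_arrays(ppv, npv, odds):
    """Vectorised contra-Bayes without feasibility gating.

    Computed from the reciprocal predictive odds so PPV or NPV equal to 1
    stay finite.  On infeasible inputs the raw algebraic values are
    returned unclamped (they fall outside [0, 1] or describe a
    worse-than-random test); callers flag them.
    """
    ppv = np.asarray(ppv, dtype=float)
    npv = np.asarray(npv, dtype=float)
    odds = np.asarray(odds, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ppo_inv = (1.0 - ppv) / ppv
        npo_inv = (1.0 - npv) / npv
        cross = 1.0 - ppo_inv * npo_inv
        sp = (1.0 - odds * ppo_inv) / cross
        sn = (1.0 - npo_inv / odds) / cross
    return sn, sp


# --------------------------------------------------------------------------
# Scalar operations
# --------------------------------------------------------------------------

def bayes_forward(tc: TestCharacteristics, prev: Prevalence) -> PredictiveValues:
    """Predictive values from (SN, SP) at a prevalence.

    Raises :class:`DegenerateTestError` when a predictive value is
    undefined (zero denominator) or zero (a test arm that is always
    wrong), since such a test has no NNT interpretation.
    """
    sn, sp, p = tc.sensitivity, tc.specificity, prev.value
    ppv_den = sn * p + (1.0 - sp) * (1.0 - p)
    npv_den = sp * (1.0 - p) + (1.0 - sn) * p
    if ppv_den == 0.0 or npv_den == 0.0:
        raise DegenerateTestError(
            f"predictive value undefined for SN={sn!r}, SP={sp!r} at prevalence {p!r}"
        )
    ppv = sn * p / ppv_den
    npv = sp * (1.0 - p) / npv_den
    if ppv == 0.0 or npv == 0.0:
        raise DegenerateTestError(
            f"degenerate test (a predictive value is exactly 0) for SN={sn!r}, SP={sp!r}"
        )
    return PredictiveValues(ppv=ppv, npv=npv)


def check_feasible(pv: PredictiveValues, prev: Prevalence) -> FeasibilityReport:
    """Evaluate the contra-Bayes feasibility margins at a prevalence."""
    odds = prev.odds
    margin_positive = pv.ppo - odds          # inf when PPV = 1
    npo_inv = 0.0 if pv.npv == 1.0 else (1.0 - pv.npv) / pv.npv
    margin_negative = odds - npo_inv
    return FeasibilityReport(
        feasible=(margin_positive > 0.0) and (margin_negative > 0.0),
        margin_positive=margin_positive,
        margin_negative=margin_negative,
    )


def contra_bayes(pv: PredictiveValues, prev: Prevalence) -> TestCharacteristics:
    """Sensitivity and specificity that reproduce ``pv`` at ``prev``.

    Feasibility (``PPO > Odds > NPO^-1``, strictly) is checked first;
    equality is treated as infeasible because one test arm would then
    carry no information.  On the feasible set the result lies in
    [0, 1]^2 and ``bayes_forward`` of the result returns ``pv``.
    """
    report = check_feasible(pv, prev)
    if not report:
        side = report.failed_side
        parts = []
        if side in ("positive", "both"):
            parts.append(
                f"PPO = {pv.ppo:.6g} does not exceed the prior odds {prev.odds:.6g} "
                "(a positive result fails to raise the probability of BestToAct)"
            )
        if side in ("negative", "both"):
            npo_inv = 0.0 if pv.npv == 1.0 else (1.0 - pv.npv) / pv.npv
            parts.append(
                f"prior odds {prev.odds:.6g} do not exceed 1/NPO = {npo_inv:.6g} "
                "(a negative result fails to lower the probability of BestToAct)"
            )
        raise InfeasibleError("infeasible predictive values: " + "; ".join(parts), failed_side=side)
    sn, sp = contra_arrays(pv.ppv, pv.npv, prev.odds)
    sn_f, sp_f = float(sn), float(sp)
    # Feasibility guarantees [0,1]^2 up to rounding at the boundary.
    eps = 1e-12
    sn_f = min(max(sn_f, 0.0), 1.0) if -eps <= sn_f <= 1.0 + eps else sn_f
    sp_f = min(max(sp_f, 0.0), 1.0) if -eps <= sp_f <= 1.0 + eps else sp_f
    return TestCharacteristics(sensitivity=sn_f, specificity=sp_f)
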