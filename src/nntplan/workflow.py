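"""Config-driven planning workflow: the six-step scaffold.

A scaffold file (YAML, or JSON — a YAML subset) records the planning
steps a design team walks through:

1. the clinical scenario (free text),
2. the principal goal (free text),
3. the intended clinical benefit (free text),
4. the elicited NNT discomfort range,
5. optionally a prospective design (cohort size, positive fraction,
   target NNTs),
6. optionally a retrospective design (cases, controls, anticipated
   counts, prevalence).

:func:`run_scaffold` turns a record into a report holding the required
predictive values, the prospective confidence intervals on both scales,
and the retrospective requirements and predictive intervals.  Reports
serialize to JSON (round-trip exact; infinities written as ``"Inf"``)
and render to markdown.  The free text travels verbatim into every
report so the intended clinical use stays attached to the numbers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources

import yaml

from .bayes_maps import Prevalence, TestCharacteristics
from .exceptions import SchemaError
from .nnt_core import (
    DiscomfortRange,
    NNTPair,
    PredictiveValues,
    format_nnt,
    format_percent,
    required_predictive_values,
    validate_discomfort_range,
)
from .study_design import (
    BinomialOutcome,
    IntervalEstimate,
    McSettings,
    ProspectiveDesign,
    ProspectiveReport,
    RetrospectiveDesign,
    RetrospectiveReport,
    prospective_summary,
    retrospective_summary,
)

__all__ = [
    "ScaffoldRecord",
    "ScaffoldReport",
    "load_scaffold",
    "run_scaffold",
    "example_scaffold_path",
]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class ScaffoldRecord:
    """A validated scaffold: three free-text steps, a range, two optional designs."""

    clinical_scenario: str
    principal_goal: str
    clinical_benefit: str
    discomfort_range: DiscomfortRange
    prospective: ProspectiveDesign | None = None
    retrospective: RetrospectiveDesign | None = None
    schema_version: int = SCHEMA_VERSION


def example_scaffold_path():
    """Path to the bundled CTCL planning example."""
    return resources.files("nntplan").joinpath("data/ctcl.yaml")


# --------------------------------------------------------------------------
# Loading
# --------------------------------------------------------------------------

def _require(mapping: dict, key: str, kind, where: str):
    if key not in mapping:
        raise SchemaError(f"missing required field '{key}' in {where}")
    value = mapping[key]
    if kind is float and isinstance(value, int) and not isinstance(value, bool):
        value = float(value)
    if not isinstance(value, kind):
        raise SchemaError(
            f"field '{key}' in {where} must be {kind.__name__}, got {type(value).__name__}"
        )
    return value


def _outcome(mapping: dict, key: str, where: str) -> BinomialOutcome:
    sub = _require(mapping, key, dict, where)
    return BinomialOutcome(
        successes=_require(sub, "successes", int, f"{where}.{key}"),
        trials=_require(sub, "trials", int, f"{where}.{key}"),
    )


def load_scaffold(path) -> ScaffoldRecord:
    """Load and validate a scaffold config (YAML or JSON).

    Numeric fields are range-checked through the same validators the
    library uses, so an elicitation with reversed NNT bounds fails here
    with the inconsistent-range diagnosis.
    """
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise SchemaError(f"scaffold file {path!r} must contain a mapping")
    version = raw.get("schema_version", SCHEMA_VERSION)
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")

    dr_raw = _require(raw, "discomfort_range", dict, "scaffold")
    dr = validate_discomfort_range(
        _require(dr_raw, "nnt_lower", float, "discomfort_range"),
        _require(dr_raw, "nnt_upper", float, "discomfort_range"),
    )

    prospective = None
    if raw.get("prospective") is not None:
        p = _require(raw, "prospective", dict, "scaffold")
        prospective = ProspectiveDesign(
            n_total=_require(p, "n_total", int, "prospective"),
            positive_fraction=_require(p, "positive_fraction", float, "prospective"),
            target=NNTPair(
                nnt_pos=_require(p, "target_nnt_pos", float, "prospective"),
                nnt_neg=(math.inf if p.get("target_nnt_neg") in ("Inf", "inf")
                         else _require(p, "target_nnt_neg", float, "prospective")),
            ),
            followup_note=str(p.get("followup_note", "")),
        )

    retrospective = None
    if raw.get("retrospective") is not None:
        r = _require(raw, "retrospective", dict, "scaffold")
        retrospective = RetrospectiveDesign(
            n_cases=_require(r, "n_cases", int, "retrospective"),
            n_controls=_require(r, "n_controls", int, "retrospective"),
            anticipated_sn=_outcome(r, "anticipated_sn", "retrospective"),
            anticipated_sp=_outcome(r, "anticipated_sp", "retrospective"),
            prevalence=Prevalence(_require(r, "prevalence", float, "retrospective")),
        )

    return ScaffoldRecord(
        clinical_scenario=str(_require(raw, "clinical_scenario", str, "scaffold")),
        principal_goal=str(_require(raw, "principal_goal", str, "scaffold")),
        clinical_benefit=str(_require(raw, "clinical_benefit", str, "scaffold")),
        discomfort_range=dr,
        prospective=prospective,
        retrospective=retrospective,
        schema_version=version,
    )


# --------------------------------------------------------------------------
# Report
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ScaffoldReport:
    record: ScaffoldRecord
    level: float
    required_pv: PredictiveValues
    prospective: ProspectiveReport | None = None
    retrospective: RetrospectiveReport | None = None

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "schema_version": self.record.schema_version,
            "level": self.level,
            "clinical_scenario": self.record.clinical_scenario,
            "principal_goal": self.record.principal_goal,
            "clinical_benefit": self.record.clinical_benefit,
            "discomfort_range": {
                "nnt_lower": self.record.discomfort_range.nnt_lower,
                "nnt_upper": self.record.discomfort_range.nnt_upper,
            },
            "required_predictive_values": {
                "ppv": self.required_pv.ppv,
                "npv": self.required_pv.npv,
            },
            "prospective": _prospective_dict(self.prospective),
            "retrospective": _retrospective_dict(self.retrospective),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(_encode_inf(self.to_dict()), **kwargs)

    @classmethod
    def from_dict(cls, d: dict) -> "ScaffoldReport":
        d = _decode_inf(d)
        dr = DiscomfortRange(**d["discomfort_range"])
        pro = _prospective_from_dict(d.get("prospective"), dr)
        retro = _retrospective_from_dict(d.get("retrospective"), dr)
        record = ScaffoldRecord(
            clinical_scenario=d["clinical_scenario"],
            principal_goal=d["principal_goal"],
            clinical_benefit=d["clinical_benefit"],
            discomfort_range=dr,
            prospective=pro.design if pro else None,
            retrospective=retro.design if retro else None,
            schema_version=d["schema_version"],
        )
        return cls(
            record=record, level=d["level"],
            required_pv=PredictiveValues(**d["required_predictive_values"]),
            prospective=pro, retrospective=retro,
        )

    @classmethod
    def from_json(cls, text: str) -> "ScaffoldReport":
        return cls.from_dict(json.loads(text))

    # -- rendering --------------------------------------------------------

    def to_markdown(self) -> str:
        r = self.record
        dr = r.discomfort_range
        lines = [
            "# Biomarker validation study plan",
            "",
            "## Step 1 — Clinical scenario",
            r.clinical_scenario.strip(),
            "",
            "## Step 2 — Principal goal",
            r.principal_goal.strip(),
            "",
            "## Step 3 — Clinical benefit",
            r.clinical_benefit.strip(),
            "",
            "## Step 4 — Classification performance needed",
            f"Elicited NNT discomfort range: ({format_nnt(dr.nnt_lower)}, "
            f"{format_nnt(dr.nnt_upper)}).",
            f"A useful test needs NNT_Pos < {format_nnt(dr.nnt_lower)} and "
            f"NNT_Neg > {format_nnt(dr.nnt_upper)}, i.e. "
            f"PPV > {format_percent(self.required_pv.ppv)} and "
            f"NPV > {format_percent(self.required_pv.npv)}.",
            "",
        ]
        if self.prospective is not None:
            p = self.prospective
            lines += [
                "## Step 5 — Prospective study",
                f"Cohort of {p.design.n_total} patients, "
                f"{format_percent(p.design.positive_fraction)} test-positive; "
                f"target NNTs ({format_nnt(p.design.target.nnt_pos)}, "
                f"{format_nnt(p.design.target.nnt_neg)})."
                + (f" Follow-up: {p.design.followup_note}." if p.design.followup_note else ""),
                f"Anticipated counts: {p.positives.successes}/{p.positives.trials} "
                f"true positives, {p.negatives.successes}/{p.negatives.trials} "
                "true negatives.",
                f"{p.level:.0%} exact confidence intervals: "
                f"PPV {format_percent(p.ppv_ci.lower)}–{format_percent(p.ppv_ci.upper)}, "
                f"NPV {format_percent(p.npv_ci.lower)}–{format_percent(p.npv_ci.upper)}; "
                f"equivalently NNT_Pos {format_nnt(p.nnt_pos_ci.lower)}–"
                f"{format_nnt(p.nnt_pos_ci.upper)}, "
                f"NNT_Neg {format_nnt(p.nnt_neg_ci.lower)}–{format_nnt(p.nnt_neg_ci.upper)}.",
            ]
            if p.clears_positive is not None:
                lines.append(
                    "The anticipated intervals "
                    + ("clear" if (p.clears_positive and p.clears_negative) else "do not clear")
                    + " the discomfort range at this sample size."
                )
            lines.append("")
        if self.retrospective is not None:
            t = self.retrospective
            d = t.design
            lines += [
                "## Step 6 — Retrospective study",
                f"{d.n_cases} cases and {d.n_controls} controls at prevalence "
                f"{format_percent(d.prevalence.value)}.",
            ]
            if t.required is not None:
                lines.append(
                    f"Required (contra-Bayes): SN {format_percent(t.required.sensitivity, 1)}, "
                    f"SP {format_percent(t.required.specificity, 1)}."
                )
            lines += [
                f"Anticipated SN = {d.anticipated_sn.successes}/{d.anticipated_sn.trials}, "
                f"SP = {d.anticipated_sp.successes}/{d.anticipated_sp.trials}; "
                f"{t.level:.0%} exact confidence intervals "
                f"SN {format_percent(t.sn_ci.lower)}–{format_percent(t.sn_ci.upper)}, "
                f"SP {format_percent(t.sp_ci.lower)}–{format_percent(t.sp_ci.upper)}.",
                f"Bayes predictive intervals (Jeffreys priors, {t.mc.n_draws} draws, "
                f"seed {t.mc.seed}): "
                f"NNT_Pos ({format_nnt(t.nnt_pos_pi.lower)}, {format_nnt(t.nnt_pos_pi.upper)}), "
                f"NNT_Neg ({format_nnt(t.nnt_neg_pi.lower)}, {format_nnt(t.nnt_neg_pi.upper)}).",
                "",
            ]
        return "\n".join(lines)


def run_scaffold(
    record: ScaffoldRecord,
    level: float = 0.95,
    mc: McSettings = McSettings(),
) -> ScaffoldReport:
    """Compute every downstream quantity the scaffold supports.

    Step 4 yields the required predictive values; step 5 (if present) the
    prospective summary; step 6 (if present) the retrospective summary
    with contra-Bayes requirements at the recorded prevalence.
    """
    required_pv = required_predictive_values(record.discomfort_range)
    pro = None
    if record.prospective is not None:
        pro = prospective_summary(record.prospective, level, record.discomfort_range)
    retro = None
    if record.retrospective is not None:
        retro = retrospective_summary(
            record.retrospective, level, mc, record.discomfort_range
        )
    return ScaffoldReport(
        record=record, level=level, required_pv=required_pv,
        prospective=pro, retrospective=retro,
    )


# --------------------------------------------------------------------------
# Dict (de)serialization helpers
# --------------------------------------------------------------------------

def _encode_inf(obj):
    if isinstance(obj, float) and math.isinf(obj):
        return "Inf"
    if isinstance(obj, dict):
        return {k: _encode_inf(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_encode_inf(v) for v in obj]
    return obj


def _decode_inf(obj):
    if obj == "Inf":
        return math.inf
    if isinstance(obj, dict):
        return {k: _decode_inf(v) for k, v in obj.items()}
    if isinstance(obj, list):
        return [_decode_inf(v) for v in obj]
    return obj


def _interval_dict(iv: IntervalEstimate | None):
    if iv is None:
        return None
    return {"lower": iv.lower, "upper": iv.upper, "level": iv.level, "method": iv.method}


def _interval_from_dict(d):
    return None if d is None else IntervalEstimate(**d)


def _prospective_dict(p: ProspectiveReport | None):
    if p is None:
        return None
    return {
        "n_total": p.design.n_total,
        "positive_fraction": p.design.positive_fraction,
        "target_nnt_pos": p.design.target.nnt_pos,
        "target_nnt_neg": p.design.target.nnt_neg,
        "followup_note": p.design.followup_note,
        "level": p.level,
        "positives": {"successes": p.positives.successes, "trials": p.positives.trials},
        "negatives": {"successes": p.negatives.successes, "trials": p.negatives.trials},
        "ppv_ci": _interval_dict(p.ppv_ci),
        "npv_ci": _interval_dict(p.npv_ci),
        "nnt_pos_ci": _interval_dict(p.nnt_pos_ci),
        "nnt_neg_ci": _interval_dict(p.nnt_neg_ci),
        "clears_positive": p.clears_positive,
        "clears_negative": p.clears_negative,
    }


def _prospective_from_dict(d, dr: DiscomfortRange):
    if d is None:
        return None
    design = ProspectiveDesign(
        n_total=d["n_total"], positive_fraction=d["positive_fraction"],
        target=NNTPair(d["target_nnt_pos"], d["target_nnt_neg"]),
        followup_note=d["followup_note"],
    )
    return ProspectiveReport(
        design=design, level=d["level"],
        positives=BinomialOutcome(**d["positives"]),
        negatives=BinomialOutcome(**d["negatives"]),
        ppv_ci=_interval_from_dict(d["ppv_ci"]),
        npv_ci=_interval_from_dict(d["npv_ci"]),
        nnt_pos_ci=_interval_from_dict(d["nnt_pos_ci"]),
        nnt_neg_ci=_interval_from_dict(d["nnt_neg_ci"]),
        discomfort_range=dr,
        clears_positive=d["clears_positive"],
        clears_negative=d["clears_negative"],
    )


def _retrospective_dict(t: RetrospectiveReport | None):
    if t is None:
        return None
    d = t.design
    return {
        "n_cases": d.n_cases,
        "n_controls": d.n_controls,
        "anticipated_sn": {"successes": d.anticipated_sn.successes,
                           "trials": d.anticipated_sn.trials},
        "anticipated_sp": {"successes": d.anticipated_sp.successes,
                           "trials": d.anticipated_sp.trials},
        "prevalence": d.prevalence.value,
        "level": t.level,
        "mc": {"n_draws": t.mc.n_draws, "seed": t.mc.seed},
        "sn_ci": _interval_dict(t.sn_ci),
        "sp_ci": _interval_dict(t.sp_ci),
        "nnt_pos_pi": _interval_dict(t.nnt_pos_pi),
        "nnt_neg_pi": _interval_dict(t.nnt_neg_pi),
        "required": (None if t.required is None else
                     {"sensitivity": t.required.sensitivity,
                      "specificity": t.required.specificity}),
        "meets_required_sn": t.meets_required_sn,
        "meets_required_sp": t.meets_required_sp,
    }


def _retrospective_from_dict(d, dr: DiscomfortRange):
    if d is None:
        return None
    design = RetrospectiveDesign(
        n_cases=d["n_cases"], n_controls=d["n_controls"],
        anticipated_sn=BinomialOutcome(**d["anticipated_sn"]),
        anticipated_sp=BinomialOutcome(**d["anticipated_sp"]),
        prevalence=Prevalence(d["prevalence"]),
    )
    return RetrospectiveReport(
        design=design, level=d["level"], mc=McSettings(**d["mc"]),
        sn_ci=_interval_from_dict(d["sn_ci"]),
        sp_ci=_interval_from_dict(d["sp_ci"]),
        nnt_pos_pi=_interval_from_dict(d["nnt_pos_pi"]),
        nnt_neg_pi=_interval_from_dict(d["nnt_neg_pi"]),
        discomfort_range=dr,
        required=(None if d["required"] is None else TestCharacteristics(**d["required"])),
        meets_required_sn=d["meets_required_sn"],
        meets_required_sp=d["meets_required_sp"],
    )
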