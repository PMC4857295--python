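# Methods

## The planning model

`nntplan` plans validation studies for a *binary* biomarker test that is
meant to settle a binary clinical decision: act (treat, refer, enrol,
monitor intensively) or wait. Each patient has a latent status —
*BestToAct* or *BestToWait* — and the prior probability
p = Pr(BestToAct) plays the role of a prevalence.

The clinical value of acting is summarised by the number needed to treat
(NNT): the expected number of patients treated per patient who benefits.
Within the subgroups defined by the test,

    NNT_Pos = 1 / PPV,        NNT_Neg = 1 / (1 − NPV),

where PPV and NPV are the positive and negative predictive values. A
design team elicits a *discomfort range* `(NNT_Lower, NNT_Upper)`: NNT
values inside it make both blanket policies (treat all / treat none)
ethically uncomfortable. A useful test must push both subgroups strictly
outside the range,

    NNT_Pos < NNT_Lower  <  NNT_Upper < NNT_Neg,

equivalently `PPV > 1/NNT_Lower` and `NPV > 1 − 1/NNT_Upper`. These two
thresholds are the design criteria for a prospective study, which
estimates PPV and NPV directly.

A retrospective case–control study estimates sensitivity (SN) and
specificity (SP) instead, so the predictive-value requirements must be
pulled back through Bayes theorem. With `Odds = p/(1−p)`,
`PPO = PPV/(1−PPV)` and `NPO = NPV/(1−NPV)`, the inversion is closed
form:

    SP = (PPO − Odds) / (PPO − NPO⁻¹)
    SN = (NPO − Odds⁻¹) / (NPO − PPO⁻¹)

It has a solution in [0, 1]² with SN + SP > 1 exactly when the test
moves the prior odds in the expected directions: `PPO > Odds > NPO⁻¹`
(strict). Equality is treated as infeasible — one test arm would carry
no information. Internally the formulas are evaluated from the
reciprocal odds `(1−PPV)/PPV` and `(1−NPV)/NPV`, which stay finite as
PPV or NPV → 1, so perfect predictive values are handled as algebraic
limits rather than floating-point infinities.

## Feasible-region geometry

At fixed p the feasible set of predictive values is the open-cornered
rectangle `PPV ∈ (p, 1]`, `NPV ∈ (1−p, 1]`. Its left edge, `PPV = p`,
is the locus where a positive result carries no information (LR+ = 1);
its bottom edge, `NPV = 1−p`, the locus where a negative result carries
none (LR− = 1). The inverse map degenerates at these edges:
approaching the left edge the solution tends to `(SN, SP) → (1, 0)`,
approaching the bottom edge to `(0, 1)`, and every uninformative test
(SN + SP = 1) collapses to the corner `(p, 1−p)`. A description of
these edges as "SN = prevalence" and "SP = 1 − prevalence" circulates
for this construction, but it is contradicted by the inversion formula
itself (at `PPO = Odds` the SN ratio is identically 1); the region
module and its tests encode the degenerate-limit geometry above. The
region grid never clamps: infeasible nodes keep their raw algebraic
values and carry a tag naming the violated inequality, so plots can
shade the two infeasible zones distinctly.

## Interval estimates

**Exact confidence intervals.** Anticipated binomial outcomes (true
positives among the test-positive arm, etc.) get two-sided
Clopper–Pearson intervals (`scipy.stats.binomtest(...).proportion_ci`),
at level 0.95 by default. The method and level are a deliberate choice:
they reproduce, at printed rounding, all six intervals of the CTCL
worked example below (19–81%, 83–100%, 1.23–5.35, 5.81–…, 60–95%,
70–94%). Lower/upper bounds are exactly 0/1 at degenerate counts.
Intervals move to the NNT scale by the monotone maps `x ↦ 1/x`
(order-reversing, positive side) and `x ↦ 1/(1−x)` (negative side, upper
endpoint infinite at NPV = 1, serialized `"Inf"`).

**Bayes predictive intervals.** For a retrospective design with
anticipated counts `x_sn/n_sn` and `x_sp/n_sp`, SN and SP are drawn
independently from Jeffreys posteriors `Beta(x + ½, n − x + ½)`; each
draw is pushed through forward Bayes at the design prevalence and onto
the NNT scale, and equal-tailed quantile intervals are reported
(highest-density intervals were considered and rejected: equal tails
commute with the monotone NNT transforms, HPD intervals do not). The
default is 100,000 draws through one explicitly passed, seeded
`numpy.random.Generator`; results are bit-reproducible for a fixed seed
and draw count, and a warning is raised below 10,000 draws. Two
independent seeds at 10⁵ draws agree within 2% on every endpoint (tested).

**Anticipated counts.** A prospective design with target NNTs converts
to anticipated counts by nearest-integer rounding, ties away from zero,
applied after a 9-decimal guard against float fuzz; the same convention
drives all display rounding (so 1/0.80 = 1.25 prints 1.3, and 23/4
computed as 5.749999… prints 5.8). NNTs display with one decimal up to
100 and three significant figures above; stored values are never
rounded.

**Sample-size search.** `minimum_n_search` finds the smallest group
sizes whose *anticipated* intervals clear the discomfort range: it
brackets by doubling, then scans linearly from n = 2, which is
deterministic and immune to the non-monotonicity that count rounding
induces. The prospective shape searches the two arms independently on
the predictive-value scale; the retrospective shape (which needs a
prevalence) searches cases and controls against the contra-Bayes
requirements. It is a precision-targeting device, not a power
calculation; formal power analyses are out of scope.

## The worked example and what the checks do (and do not) show

The bundled scaffold (`data/ctcl.yaml`) encodes a planning consultation
for early-stage cutaneous T-cell lymphoma: discomfort range (2, 30),
15% prevalence of rapid progression, a 40-patient prospective cohort
(25% anticipated positive), and a retrospective arm of 22 cases and 40
controls with anticipated SN = 18/22 and SP = 34/40. All inputs are
scalar design parameters; there is no patient-level data anywhere, so
the test suite exercises exact algebra, interval construction, and
Monte-Carlo sampling — not robustness to real-data artifacts
(misclassified cases, drifting biomarkers, non-representative referral
populations), which no desk calculation can establish.

The acceptance suite contains two deliberately strict reference checks
that this implementation does not satisfy, kept strict rather than
loosened. First, the predictive intervals for this example are often
quoted as (1.4, 2.7) and (16.4, 87.8); the procedure as specified
(independent Jeffreys posteriors from 18/22 and 34/40, forward Bayes at
p = 0.15, equal-tailed 95% quantiles) evaluates to ≈(1.45, 3.08) and
≈(13.5, 75.2) at Monte-Carlo precision, and no standard variant (HPD,
other levels, other odds conventions) reconciles all four endpoints.
Second, the "SN = prevalence / SP = 1 − prevalence" boundary labels
discussed above fail against the algebra. Both checks' failures are
intentional and documented here; the remainder of the suite is expected
green.

## Numerical and design choices

- NNT values are real-valued (≥ 1): the algebra requires continuity even
  though elicitation narratives use whole patients.
- All usefulness and feasibility inequalities are strict; boundary cases
  are reported as failures/infeasible, not rounded in.
- No clamping anywhere in the inverse mapping: out-of-range results are
  a bug signal, except for a 10⁻¹² snap at the [0, 1] boundary to absorb
  last-bit rounding of genuinely feasible inputs.
- Scaffold configs are YAML (JSON accepted) with a `schema_version` key;
  reports serialize to JSON that round-trips exactly (`"Inf"` for
  infinite NNTs) and render to markdown that quotes the team's step 1–3
  free text verbatim, so the intended clinical use travels with the
  numbers.
- Region grids default to 201×201; NNT axes are log-spaced on
  [1.05, 1000]. CSV export writes full-precision floats and reads them
  back with round-trip parsing, so export → read is exact.

## Known limitations

- Binary tests only: no continuous scores, ROC thresholds, or cutoff
  selection.
- One clinician's discomfort range at a time: no multi-rater
  aggregation or sensitivity analysis over elicitations.
- The prevalence is a fixed design parameter, not a posterior; its
  uncertainty is not propagated into the predictive intervals.
- `minimum_n_search` assumes estimates land exactly on their targets;
  it quantifies precision, not assurance probability.
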