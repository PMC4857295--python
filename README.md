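# nntplan

Planning biomarker validation studies on the **number-needed-to-treat
(NNT)** scale.

Most biomarker validation studies are sized and judged on statistical
criteria — p-values, hazard ratios, sensitivity/specificity — that say
little about whether the test would change decisions for patients.
`nntplan` is for biostatisticians and clinical study teams who want to
anchor a validation design to an explicit clinical-usefulness criterion
before choosing sample sizes.

## The model

A binary test should resolve a binary decision: act or wait. The team
elicits an NNT *discomfort range* `(NNT_Lower, NNT_Upper)` — the NNTs
for which neither treating everyone nor treating no one is comfortable.
A useful test must split patients into subgroups falling strictly
outside it:

```
NNT_Pos < NNT_Lower < NNT_Upper < NNT_Neg
```

Since `NNT_Pos = 1/PPV` and `NNT_Neg = 1/(1−NPV)`, the range converts
directly to required predictive values — the design criteria for a
**prospective** cohort study. A **retrospective** case–control study
estimates sensitivity and specificity instead, so the requirements are
pulled back through an exact inversion of Bayes theorem: with
`Odds = p/(1−p)`, `PPO = PPV/(1−PPV)`, `NPO = NPV/(1−NPV)`,

```
SP = (PPO − Odds) / (PPO − NPO⁻¹)
SN = (NPO − Odds⁻¹) / (NPO − PPO⁻¹)
```

valid whenever `PPO > Odds > NPO⁻¹`. Around this core the package
provides exact (Clopper–Pearson) confidence intervals for anticipated
results, their NNT-scale transforms, Monte-Carlo Bayes predictive
intervals for NNT under Jeffreys priors, feasibility-region grids, a
minimum sample-size search, and a config-driven six-step planning
workflow with markdown/JSON reports. See `docs/methods.md` for the full
account.

## Worked example

A consultation on early-stage cutaneous T-cell lymphoma (CTCL): about
15% of early-stage patients progress rapidly and would benefit from
aggressive up-front therapy. The team's discomfort range is (2, 30), so
the test must achieve PPV > 50% and NPV > 97%. What sensitivity and
specificity must a case–control study demonstrate?

```console
$ nntplan contrabayes --ppv 0.5 --npv 0.96667 --prevalence 0.15
SN 83.3%
SP 85.3%
```

A test with SN = SP = 80% at a 5% prevalence, for comparison:

```console
$ nntplan forward --sn 0.8 --sp 0.8 --prevalence 0.05
PPV 17%  NPV 99%
NNT_Pos 5.8  NNT_Neg 77.0
```

— treating all test-positives means treating 5.8 patients per true
rapid progressor, while withholding among negatives forgoes one benefit
per 77 patients.

Anticipated precision of the planned case–control arm (22 cases, 40
controls, anticipated SN = 18/22, SP = 34/40), with Bayes predictive
intervals for the subgroup NNTs:

```console
$ nntplan retrospective --sn-x 18 --sn-n 22 --sp-x 34 --sp-n 40 \
      --prevalence 0.15 --nnt-lower 2 --nnt-upper 30 --seed 1
SN CI 60%-95%  SP CI 70%-94%
NNT_Pos PI (1.5, 3.1)  NNT_Neg PI (13.5, 75.6)
required SN 83.3%, SP 85.3%
```

The anticipated SN of 81.8% falls short of the required 83.3% — exactly
the kind of tension the scaffold is meant to surface before the study
runs. The whole six-step plan, including the prospective arm, runs from
the bundled config:

```console
$ nntplan scaffold run src/nntplan/data/ctcl.yaml --seed 1
```

which reports, among other things, the prospective 95% intervals
PPV 19–81% and NPV 83–100% (NNT_Pos 1.2–5.3, NNT_Neg 5.8–1190) for a
40-patient cohort — far too wide to clear the range, motivating the
retrospective design. The same API is available from Python
(`nntplan.contra_bayes`, `nntplan.run_scaffold`, …).

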