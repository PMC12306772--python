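# Methods

`lungscreen-cea` reimplements, as a tested Python package, a published
decision-analytic evaluation of one-off liquid-biopsy screening
(a seven-autoantibody ELISA panel) for lung cancer in a high-risk
population, assessed from a public-payer perspective.  This note records the
model, its conventions, and the design choices made where the published
description left the mechanics open.

## Model structure

A decision tree resolves the diagnostic moment; a Markov cohort model
carries its terminal nodes over a lifetime horizon.

**Decision tree.**  With prevalence π, test sensitivity *se*, specificity
*sp*, early-stage fraction among screen-detected cancers *q_s* and among
clinically detected cancers *q_c*, the screening arm splits into six
branches — TP-early (π·se·q_s), TP-advanced (π·se·(1−q_s)), FN-early
(π·(1−se)·q_c), FN-advanced (π·(1−se)·(1−q_c)), FP ((1−π)(1−sp)) and TN
((1−π)·sp) — and the no-screening arm into three (π·q_c, π·(1−q_c), 1−π).
False negatives follow the clinical pathway (same stage mix, same
downstream costs) plus the test cost.  All diagnosis happens at cycle 0;
no repeat or interval screening is modelled, and no incident cancers arise
after baseline.

**Markov model.**  Four states: `no_cancer`, `early_stage`,
`advanced_stage`, `dead`; one-year cycles from the cohort's initial age
(61.9 years) to age 100, stopping early if alive mass falls below 1e-9.
`no_cancer` dies at the life-table probability for the current (floored)
age.  Cancer states die at constant annual probabilities
`p = 1 − exp(−r)`, with `r = −ln(S₅)/5` from five-year overall survival
(53.5% early → r = 0.1251; 3.9% advanced → r = 0.6488).  Early→advanced
transitions are not modelled: stage-at-diagnosis survival statistics
already integrate later progression.  Because the stage-specific rates
derive from all-cause survival, background mortality is *not* added on top
(the `add_background_hazard` flag enables it for exploration; default off,
to avoid double-counting deaths).

## Accrual, half-cycle correction, discounting

Cycle *t* accrues on the trapezoidal mean membership
m̄ = ½(m_t + m_{t+1}) — the conventional half-cycle correction — for both
QALYs (Σ_state m̄·u_state) and recurring costs.  Accruals are discounted to
the cycle midpoint, `(1+d)^−(t+½)`, the timing consistent with mid-cycle
membership; end-of-cycle discounting `(1+d)^−(t+1)` is available via
`ModelSettings(discount_timing="end")` and changes totals by under 3%.
Upfront tree costs are cycle-0 point masses, undiscounted.  The base
discount rate is 5%/year (0–10% in sensitivity analysis).

## Cost accounting

Three upfront cost items: the liquid-biopsy price (US$419.08, every
screened individual including false negatives), a diagnostic work-up
(LDCT + PET-CT) for every positive test or clinical suspicion, and an
invasive staging work-up (bronchoscopy + percutaneous biopsy) for
advanced-stage diagnoses.  The diagnostic (US$415.23) and staging
(US$24.40) entries are federal SIGTAP reimbursements covering only the
federal share of public expenditure; the model multiplies them by the
table adjustment factor (base 2.84, varied 1–3.12 in sensitivity analysis)
to approximate the full cost.  We read the factor as a multiplier on the
raw SIGTAP entries rather than a ratio around an already-adjusted cost:
this is the reading consistent with the published totals, and it makes the
factor a genuine lever in the tornado analysis.  The biopsy price and the
treatment costs come from market/microcosting sources and are not scaled.

Recurring annual treatment costs accrue per cycle while alive in a cancer
state: early-stage pays treatment (US$874.65) plus chemotherapy
(US$167.12) — the chemotherapy row is charged to early-stage only, since
the advanced-stage microcosting source already includes pharmaceutical and
palliative-drug expenditure — and advanced-stage pays US$2,135.81/year.
`no_cancer` accrues no cost.

## Parameters and distributions

The bundled fixture (`table1_base_case.yaml`) carries all 19 parameters
with base value, (lower, upper) range, and distribution family.  For PSA
sampling, Beta and Gamma distributions are moment-fitted treating
(lower, upper) as a symmetric 95% interval, `sd = (upper−lower)/3.92`;
this reproduces the base value as the distribution mean exactly.  Uniform
parameters sample on [lower, upper]; the Normal initial age is truncated
to its bounds so no impossible age can be drawn; zero-width intervals are
point masses.  By default **every** parameter with a declared distribution
is sampled, including the discount rate (Uniform 0–0.10) and the
adjustment factor (Uniform 1–3.12): the published uncertainty analysis
declares distributions for all rows, and the resulting per-draw ICER
median and 2.5–97.5 percentile spread match the published summary closely,
where holding the two methodological rows fixed yields a visibly too
narrow spread.  `run_psa(..., exclude=METHODOLOGICAL_PARAMETERS)` restores
the stricter convention.  One common draw feeds both strategy arms per
iteration; draws are consumed in a fixed parameter order from a single
seeded generator, so results replay bit-identically from (inputs, seed).

The per-draw "median ICER" is the median of ΔC/ΔE over draws with ΔE > 0;
dominance draws are counted separately (the ratio is meaningless there).

## Threshold and scenario analyses

The prevalence threshold bisects ICER(π) = WTP on π ∈ (0.005, 0.20) with
absolute tolerance 1e-4 and at most 60 iterations; ICER(π) is monotone
decreasing (verified by grid sweep), and an absent sign change returns a
no-crossing result rather than raising.  The default WTP is the upper
national threshold, US$21,052.62/QALY (US$7,017.54 lower).  The
`inca_survival` scenario replaces the five-year survival basis with 25.0%
(early) and 2.5% (advanced) — national-registry figures — through the same
exponential conversion, leaving everything else at base.

## Synthetic life table

Background mortality uses a Gompertz–Makeham hazard
μ(x) = c + a·e^{bx} with defaults c = 0.002, a = 3e-5, b = 0.095,
max age 100 (q(62) ≈ 0.0128, strictly increasing; terminal qx = 1).  It
emulates the *shape* of middle-income-country adult mortality, not any
official national table: levels at higher ages are somewhat lighter than
the 2017 national tables the original analysis used, which inflates the
absolute QALY totals of both arms by a few percent while leaving the
*incremental* results essentially untouched (cancer-state mortality, not
background mortality, drives the increment).  Passing tests on the
synthetic table therefore validate the engine and the incremental
economics, not country-specific absolute life expectancy.  Any real
`age,qx` CSV can be supplied with `--life-table` without code changes.

## Numerical choices

- Branch probabilities must sum to 1 within 1e-12; per-cycle occupancy is
  conserved to the same tolerance and checked at runtime (1e-9 guard).
- Life-table lookup is by floor(age); fractional initial ages are allowed.
- The horizon is ⌈max_age − initial_age⌉ cycles; remaining survivors at
  the cap are truncated (their discounted weight is negligible).
- Beta moment fits reject sd² ≥ mean(1−mean) (infeasible moments) and
  zero-width intervals (degenerate point masses) with specific errors.
- The microsimulation oracle mirrors the cohort engine event-for-event
  (same death probabilities, trapezoidal half-weight in the death cycle)
  and is used only as a statistical cross-check of the expectation.

## Known limitations and reproduction quality

Reconstructed from a published description whose spreadsheet internals are
unavailable, the package reproduces the published incremental cost,
incremental effectiveness, screening-arm total cost and ICER to ~1%, the
prevalence threshold within 0.7 percentage points, and the PSA median and
spread within a few percent (see `scripts/acceptance.py`).  Two figures
resist reconstruction: the no-screening arm's total cost comes out ~9%
below the published value (the published screening total and increments
are internally consistent with ours, implying an unexplained extra cost
component in the original no-screening arm), and the alternative-survival
scenario's ICER comes out ~15% above (the discrepancy is uniform across
the scenario's published prevalence range, suggesting the original
survival machinery under those inputs departs from the documented pure
exponential).  Both are reported as computed.

Out of scope by design: LDCT comparators, overdiagnosis/indolent tumours,
diagnostic adverse events, repeat screening rounds, stage-progression
tunnel states, currency conversion/inflation adjustment, and EVPI.
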