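# Methods

## Model

`markovcea` implements a cost-utility analysis of three biologic
(TNF-inhibitor) strategies for rheumatoid arthritis — Infliximab,
Adalimumab and Etanercept — as a Markov cohort state-transition model.
Disease activity is tracked through DAS-28 bands, which define four
living states plus an absorbing death state:

| state     | DAS-28 band |
|-----------|-------------|
| Remission | < 2.6       |
| Low       | 2.6 – 3.2   |
| Moderate  | 3.2 – 5.1   |
| Severe    | > 5.1       |
| Death     | —           |

The cohort is a probability vector over these states, propagated each
cycle by a row-stochastic 5×5 transition matrix `P`:
`x_{t+1} = x_t P`. The published transition table covers only the living
rows; the absorbing row (0,0,0,0,1) is appended, and death is the only
exit (no background life-table mortality). Cycles are three months
(Δ = 0.25 y) and the run continues to `max_cycles` (default 400, i.e.
100 years — a lifetime-horizon proxy) or until the living mass falls
below 1e-9.

Rewards are attributed to the occupancy at the **start** of each cycle;
when half-cycle correction is enabled the mean of adjacent occupancy
rows is used instead (off by default — the source analysis gives no
indication one was applied). Discounting is continuous in cycles with
elapsed time `tΔ`, so the per-cycle factor is `(1+r)^(-tΔ)`, exact at
year boundaries; costs discount at 5.8 %/y and outcomes at 3 %/y.

Discounted totals per strategy:

- cost = Σ_t Σ_s occ[t,s] · c_s · (1+r_c)^(−tΔ)
- QALY = Σ_t Σ_s occ[t,s] · u_s · Δ · (1+r_o)^(−tΔ)

with `u_Death = 0` and `c_Death = 0` fixed. Both sums are evaluated as
dot products against precomputed per-state trace weights; the
deterministic evaluation, the tornado analysis and the probabilistic
analysis all share this kernel, which is why a probabilistic run with
all variances collapsed to zero reproduces the deterministic table
bit-exactly.

### State costs

The cost tables report annual per-patient component totals (visits,
medication, tests, physiotherapy/other, diagnostics, injection;
transportation, accommodation, meals; lost revenue), not per-state
costs. The default therefore spreads the annual total uniformly over
the living states (`c_s = total × Δ`). An optional `state_cycle_costs`
table per strategy overrides the uniform allocation for users who want
state-dependent costing; both modes flow through every analysis.

### Initial distribution and non-identifiability

The cohort starts 100 % Severe by default: DAS-28 > 5.1 is the
threshold at which biologic therapy is initiated. This, the state-cost
mapping and the horizon are exactly the internals the source report
does not pin down, so the engine's absolute totals are **not** claimed
to equal the published per-arm totals (they do not, under the defaults).
All three are plain configuration. The published per-arm (cost, QALY)
table ships with the fixture as `reference_results` and is used as input
to the ranking layer, where the desk-scale arithmetic (incremental
costs, the 13,420 $/QALY ICER, the dominance pattern) is reproduced.

## Economic evaluation

ICER = (Cost_A − Cost_B)/(QALY_A − QALY_B); an equal-outcome pair has no
ICER (`nan`) and is decided by cost. Ranking sorts strategies by
ascending cost, removes absolutely dominated strategies (weak dominance
counts: no cheaper-or-equal strategy with at least as many QALYs may
exist; exact ties break by name), then iteratively removes extendedly
dominated strategies until sequential ICERs along the frontier are
non-decreasing — equivalent to the lower-left convex hull, and tested
against an independent hull-enumeration oracle. WTP verdicts follow the
WHO convention with GDP per capita $12,547 (PPP, 2019): ICER < 1×GDP is
highly cost-effective, < 3×GDP cost-effective, otherwise not; bounds are
exclusive. Net monetary benefit is `QALY·λ − cost`.

## Sensitivity analyses

**One-way (tornado).** Every cost parameter and every state-utility
mean of the two compared strategies is set to 0.8× and 1.2× of its base
value in turn, everything else fixed, and the pairwise ICER is
re-evaluated; entries are ordered by descending width. Utility means are
not clamped during perturbation (the reward is linear in the mean), and
a component that is zero at base is retained as a zero-width bar.

**Probabilistic (PSA).** Second-order Monte Carlo, 5,000 trials by
default: one draw of every parameter per trial, shared across the
evaluation, no first-order patient noise. Utilities draw from beta
distributions moment-matched to the reported (mean, SD):
`α = mν, β = (1−m)ν, ν = m(1−m)/s² − 1`; costs draw from gammas
(`shape = m²/s², rate = m/s²`). Cost SDs are not reported, so a
coefficient of variation of 0.2 is assumed (configurable), mirroring the
±20 % one-way perturbation scale. A utility SD at or beyond the beta
feasibility bound √(m(1−m)) is shrunk to 0.99× the bound with a warning;
a mean outside (0,1) with positive SD fails before any sampling. One
seeded `numpy` generator drives the run, sampling in lexicographic
(strategy, parameter) order — results are bit-reproducible from the
seed.

The CEAC reports, per WTP value on a grid (0 to 3×GDP, 1×GDP always a
grid point), the fraction of trials in which each strategy attains the
maximal NMB; exact ties split equally, so the probabilities sum to 1.
Pairwise scatter acceptance is the fraction of trials with strictly
positive incremental NMB (ties count as not accepted).

## Synthetic cohort

The generator emulates the study's patient-level data: per arm
(n = 53/48/53 by default), a DAS-28 band from the arm's categorical
response distribution, a utility from the band's beta, and each annual
cost component from its gamma (same CV policy). The published response
table pools DAS-28 > 3.2; the fixture splits that count near-evenly
between Moderate and Severe (extra patient to Moderate) since the model
distinguishes them — the pooled count remains recoverable as their sum.
Utilities are generated directly on [0,1] per band; the EQ-5D instrument
and national tariff are not simulated. Components are sampled
independently — no cost–cost or cost–utility correlation — so passing
recovery tests demonstrate estimator consistency under the assumed
independent parametric families, not robustness to the correlation
structure or measurement error of real claims/interview data.

Summaries reproduce the table-style statistics (band counts and
2-decimal percentages, per-band utility mean and n−1 SD, cost category
totals satisfying DMC + DNMC + IC = total, component shares within
category). Recovery estimates band proportions, utility moments and
cost means; a band with fewer than two records is flagged rather than
imputed, and flagged estimates refuse to re-enter the pipeline.

Recovery accuracy at a given cohort size is limited by band thinning:
a band holding ~4 % of an arm has ~400 patients even at n = 10,000/arm,
leaving a utility-mean standard error near 0.01. The recovery test
therefore averages recovered estimates over 20 replicate cohorts, which
checks unbiasedness at that n rather than the luck of one draw.

## Numerical choices

- Transition rows must sum to 1 within 1e-9 (the printed rows sum to
  exactly 1.000); the death row must be exactly absorbing.
- Early stop at living mass < 1e-9; trace equivalence with the
  matrix-power oracle holds to 1e-12 for t ≤ 50.
- Printed category totals are cross-checked against component sums with
  a ±0.02 rounding allowance; the one larger discrepancy in the source
  table (8.99 in the Etanercept direct-medical column) is surfaced as a
  warning and the components are kept as printed.
- CSV outputs serialize at 6 significant digits; currency fields in the
  decision JSON are rounded to cents.
- CLI exit codes: 0 success, 2 configuration/usage error, 3 numeric or
  distribution-feasibility error.

## Known limitations

- Cohort expectation only; no microsimulation, no parameter correlation
  (copulas), no EVPI/EVPPI, no budget impact.
- The only mortality pathway is the transition table's death column.
- Absolute engine totals depend on unidentified internals of the source
  analysis (initial distribution, state-cost mapping, horizon); they are
  exposed as configuration, and no setting is claimed to recover the
  published per-arm totals.
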