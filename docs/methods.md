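# Methods

## The decision problem

The model compares two first-line strategies for advanced NSCLC without
EGFR/ALK/ROS1 alterations: cemiplimab 350 mg every 3 weeks (for up to
108 weeks) plus up to four cycles of histology-matched platinum-doublet
chemotherapy (CCT), versus the same chemotherapy with placebo (PCT).
Patients with a pemetrexed-containing doublet continue pemetrexed
maintenance while progression-free; all patients receive best supportive
care after progression until death. The perspective is the Chinese
healthcare system, 2022 US dollars, and the decision rule is the ICER
against a willingness-to-pay threshold of $38,201/QALY (three times 2022
GDP per capita).

## Survival model

Both endpoints (overall survival, OS; progression-free survival, PFS)
follow Weibull laws on the hazard scale,

    S(t) = exp(−λ t^γ),    hazard h(t) = λ γ t^(γ−1),

with t in **months** (1 month = 30.4375 days). The placebo-arm
parameters are

| curve | λ (per month^γ) | γ |
|---|---|---|
| PFS, PCT | 0.061800 | 1.388300 |
| OS, PCT | 0.030040 | 1.213530 |

which imply medians of ≈ 5.7 months (PFS) and ≈ 13.3 months (OS),
consistent with the trial's reported 5.0 and 13.0 months — this is what
fixes the monthly time unit: on a per-cycle or per-day scale the same
numbers are off by an order of magnitude. The intervention arm is
derived under proportional hazards with a shared shape: λ_CCT = HR × λ_PCT,
γ_CCT = γ_PCT, using the trial hazard ratios 0.56 (PFS, 95% CI
0.44–0.70) and 0.71 (OS, 0.53–0.93). Under a shared γ this is exact:
the hazard ratio is constant in time.

Where the placebo-arm parameters are instead re-estimated from a
published figure, the pipeline reconstructs pseudo-individual patient
data from digitized curve coordinates and the numbers-at-risk row
(iterative interval algebra: censorings spread uniformly within each
risk interval, integer event counts solved to match both the curve's
drops and the at-risk decline), then fits exponential, Weibull,
log-logistic and log-normal laws by censored maximum likelihood and
selects by AIC (ties: BIC, then family order). Two reconstruction
details matter and are easy to get wrong:

- **Boundary attribution.** A curve drop printed exactly at a
  numbers-at-risk time represents events just *before* that time, which
  the printed at-risk count already excludes; risk intervals are
  therefore left-exclusive/right-inclusive. The boundary-inclusive
  reading manufactures spurious censorings (roughly one digitization
  step's worth of events per interval) and visibly distorts the refit.
- **Step-corner coordinates.** The synthetic digitizer places extracted
  points at the curve's actual step corners (what an operator clicks),
  not on a fixed resampling grid; snapping event times to a regular grid
  biases the refitted hazard-scale λ downward by ≈ 25% at a 1-month
  grid.

## Cohort model

Three health states — progression-free (PFS), progressed (PD), dead —
on a 21-day cycle grid (one treatment cycle), starting fully
progression-free, until 99% of the (slower-dying) cohort is dead or 120
cycles (≈ 6.9 years), whichever is first. Three transition structures
are implemented; all satisfy the same occupancy invariants (sum to 1
within 1e-9, death non-decreasing, PFS non-increasing):

- **`markov` (default).** Per cycle, PFS occupants leave at the PFS
  exit probability 1 − S_PFS(t)/S_PFS(t−Δ) and *all exits enter PD*;
  PD occupants die at the per-cycle OS probability
  1 − S_OS(t)/S_OS(t−Δ). Death is reached only through progression, so
  cumulative death lags 1 − S_OS.
- **`partitioned`.** Classic partitioned-survival reading:
  pfs = S_PFS, dead = 1 − S_OS, pd = max(0, S_OS − S_PFS).
- **`state_transition`.** As `markov` but with PFS exits split between
  PD and death and the PD→death probability calibrated each cycle so
  cumulative death tracks 1 − S_OS exactly (its death column equals
  `partitioned`'s).

Why `markov` is the default: the published per-arm life-years and QALYs
are arithmetically incompatible with any structure whose death column is
anchored to 1 − S_OS (those yield ≈ 1.37 / 1.82 undiscounted life-years
for PCT / CCT), but are reproduced to within a few percent by the
`markov` bookkeeping (≈ 1.81 / 2.47 vs the published 1.83 / 2.49). The
published analysis was built in a graphical Markov-cohort tool, and this
sequential PFS→PD→death chain is evidently the transition logic it
encoded. The other two structures are retained because partitioned
survival is the defensible textbook reading of two published curves;
results under all three are one settings switch apart
(`ModelSettings(structure=...)`).

With the default structure the two curves are used only through their
per-cycle ratios, so subgroups whose OS hazard ratio exceeds 1 (PFS
curve nosing above OS) pose no difficulty; the curve-based structures
validate against crossing beyond a 1e-6 tolerance and clamp inside it
(the model evaluator relaxes this check for subgroup work).

No half-cycle correction is applied by default — the published analysis
gives no indication of one — but `ModelSettings(half_cycle=True)`
switches all accrual to mid-cycle (start/end average) occupancy.

## Costs, utilities, accrual

Direct medical costs only. Per cycle: PFS occupancy pays drug cost plus
routine follow-up ($92.69); PD occupancy pays best supportive care
($365.51); newly dead pay end-of-life care ($2,665.11). Drug costs use
exact per-mg pricing (no vial rounding) with doses pemetrexed 500 mg/m²,
paclitaxel 200 mg/m², cisplatin 75 mg/m² at body surface area 1.72 m²,
carboplatin by the Calvert formula AUC 5 × (CrCl 70 + 25) = 475 mg, and
cemiplimab a flat 350 mg. Chemotherapy cost in cycles 1–4 is the
regimen-mix-weighted doublet cost (mix per arm as observed in the
trial); from cycle 5 only the pemetrexed-regimen fraction pays
pemetrexed maintenance (uncapped while progression-free); cemiplimab is
charged for CCT-arm PFS occupancy through cycle 36 (108 weeks).
Cemiplimab has no Chinese list price, so its unit price assumes
per-cycle parity with pembrolizumab: 2662.41 × 200/350 = $1521.38 per
100 mg.

Grade ≥3 treatment-emergent adverse events with >5% incidence (anemia,
neutropenia) carry one-time, incidence-weighted costs and one-cycle
utility decrements at model entry. Utilities are 0.804 (PFS) and 0.321
(PD). QALYs accrue as occupancy × utility × cycle length in years; every
cost and QALY is discounted at 5%/year, continuously compounded per
cycle end time, (1.05)^(−t/365.25). Life-years are reported both
discounted and undiscounted (the publication does not say which it
prints; its values match the undiscounted reading). End-of-life cost is
applied to all deaths (whether it applied only to post-progression
deaths is unstated; under the default structure all deaths are
post-progression anyway).

ICERs preserve sign: a costlier strategy that loses QALYs reports the
negative ratio with a `dominated` annotation rather than an absolute
value.

## Uncertainty analysis

**One-way (tornado).** Each parameter in turn to the ends of its range —
trial 95% CIs for hazard ratios; ±20% of base elsewhere, including the
four placebo-arm Weibull parameters — with everything else at base;
entries sorted by ICER spread. The dominant drivers are the OS hazard
ratio, the cemiplimab unit price and the PFS hazard ratio.

**Probabilistic (PSA).** 1,000 Monte-Carlo iterations redraw all Table
parameters jointly and independently: gamma for costs and creatinine
clearance, beta for probabilities/utilities/disutilities/regimen
proportions, normal truncated at zero for hazard ratios and body surface
area, with distributions moment-matched to (base, sd) where
sd = (high − low)/3.92 (the printed range read as a 95% interval;
multiplier configurable). Regimen proportions are renormalised to sum to
one after sampling. The discount rate is fixed in the PSA, and the
Weibull parameters enter only the one-way analysis (no distributional
assignment exists for them). The acceptability curve is the fraction of
iterations with positive net monetary benefit, NMB = WTP·ΔQALY − ΔCost,
computed from a single PSA sample across the WTP grid. Draws are
reproducible bit-for-bit per seed.

**Price threshold.** Two solvers return the cemiplimab price per 100 mg
at which CCT becomes acceptable at $38,201/QALY: a closed-form solve of
the affine deterministic equation ICER(price) = WTP (total cost is affine
in every unit price), and a bisection on the price until PSA
acceptability is within 1 percentage point of 50% (fixed seed, n ≥ 1000).
The two agree within a few percent; both sit near 12–14% of the baseline
price.

**Subgroups.** All 21 trial subgroups substitute their own PFS/OS hazard
ratio point estimates (used as printed, even where the CI crosses 1) into
the intervention-arm derivation; every other parameter stays at the
whole-population value.

## Synthetic data

The generator draws event times by inverse transform from the configured
Weibull laws (defaults: the placebo-arm OS/PFS laws above, 154 patients,
24 months administrative censoring, 1%/month exponential dropout) and
emulates figure digitization as described under *Survival model*
(step-corner coordinates rounded to 3 decimals, numbers-at-risk every
3 months). It captures what the reconstruction needs — step geometry,
at-risk bookkeeping, rounding — but not digitization pointing error
beyond optional uniform jitter, reader disagreement, or correlated
PFS/OS at patient level (endpoints are simulated as independent
marginals). Passing round-trip tests therefore demonstrate algorithmic
correctness on clean and mildly noisy figures, not robustness to badly
digitized ones.

## Numerical conventions and edge cases

- Digitized survival inputs are repaired to non-increasing by running
  minimum; repairs larger than 0.005 log a warning.
- Fits use lifelines' censored MLE; on non-convergence, up to three
  perturbed restarts, then an explicit error (never silent defaults).
  Exponential fits are checked against the closed-form rate n/T.
- AIC = 2k − 2ℓ and BIC = k·ln n − 2ℓ exactly, k = free parameters.
- A zero ΔQALY yields an undefined-ICER sentinel, never a division by
  zero; PSA iterations that violate model invariants are rejected and
  logged, and a run fails if more than 1% are rejected.
- Problem sizes: 120 cycles per trace, 1,000 PSA iterations, 20-replicate
  recovery studies at n = 500, one 20,000-draw fixture for tight
  parameter-recovery bounds.

## Known limitations

- The published analysis's software conventions (half-cycle handling,
  exact horizon, LY discounting) are not printed; the default
  configuration reproduces its headline numbers to within ≈ 8% but not
  to printed precision, and the structure switches exist precisely to
  explore that residual gap.
- Hazard-ratio scaling assumes proportional hazards with shared shape
  throughout; no time-varying hazard ratios, spline or cure-fraction
  extrapolations.
- Costs are 2022 USD as given; no inflation indexing, vial sharing or
  wastage modelling, and no societal perspective.
- Subgroup results inherit the whole-population cost/utility inputs and
  point hazard ratios; they are exploratory, as in the source analysis.
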