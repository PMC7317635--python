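# Methods

This note documents the model, its assumptions, the synthetic-data
generator, and the numerical choices, in the order a reader auditing the
results would need them.

## Model structure

The engine is a proportional multistate life table: one main life table
per population stratum (sex × ethnicity), plus one parallel life table
per disease. Cohorts are indexed by single year of age at baseline
(0–109) and advance on annual cycles until the terminal age of 110,
where any remaining survivors die in the final cycle. The population is
closed — no births, no migration — matching a "population alive at
baseline, followed until death" design.

Rates are treated as annual transition probabilities (the synthetic
generator guarantees values below 1). Within a cycle, disease
transitions resolve in a fixed order: **case fatality → remission →
incidence**. Newly remitted people are not re-exposed to incidence in
the same cycle, and new incident cases are not exposed to case fatality
in their onset year. This ordering is a declared approximation (the
original spreadsheet lineage of such models does not pin it down
publicly); it is exactly reproduced by the Markov matrix-powering oracle
in the test suite, so any change in convention will be caught.

Disease prevalence among the living is π = C/(S+C); the disease's
contribution to stratum mortality is π·f and to morbidity dw·π, where dw
is a per-disease disability weight. Intervention-vs-BAU differences are
transferred additively to the main table:

    q_int(a,t)   = q_bau(a) − Σ_d [m_d_bau(t) − m_d_int(t)]
    pyld_int(a,t)= pyld_bau(a) − Σ_d dw_d·[π_d_bau(t) − π_d_int(t)]

with results clipped to [0, 1) and every clip counted (the default
scenario triggers none; the test suite asserts this). BAU outputs never
depend on intervention parameters, and the bundle caches the BAU run
across scenario and Monte Carlo evaluations.

**Initial prevalence.** Each cohort starts with the disease prevalence
implied by a period run of its own rates from age 0, rather than zero.
This keeps baseline disease person-time realistic for older cohorts;
because results are BAU-vs-intervention differences, the choice shifts
levels far more than differences.

**Life years.** No half-cycle correction by default: a year counts only
if survived, L(t) = l(t+1) (the `half_cycle` flag switches to the
midpoint convention). The convention cancels almost entirely in the
scenario difference.

**Diabetes as a risk factor.** The engine exposes no
diabetes-to-CHD/stroke multiplier in v1; the five diseases are
independent conditional on exposure. This is a known simplification of
the disease-independence assumption shared by this model family.

## Exposure, relative risk, and PIFs

Weekly MVPA MET-minutes are held as 8 fixed bins
(0, 1–149, 150–299, 300–599, 600–1199, 1200–2399, 2400–4799, ≥4800)
with midpoints (0, 75, 225, 450, 900, 1800, 3600, 6000). A binned
distribution makes the population impact fraction an exact finite sum;
relative risks are evaluated at bin midpoints (no within-bin
integration — the error is absorbed by bin granularity).

Relative risk is log-linear and protective: RR(e) = max(floor,
exp(−β·e)), anchored at RR = 1 for zero activity, floored at 0.5. The
slopes are synthetic placeholders with the conventional qualitative
shape (monotone non-increasing, strongest for type 2 diabetes and CHD,
weaker for the cancers); published magnitudes live in technical
appendices that are out of scope here, so no claim is made that the
synthetic slopes reproduce any published risk curve.

The intervention shifts the affected fraction of every bin's mass to the
bin containing (midpoint + Δ); the top bin absorbs overflow; mass is
conserved exactly. Negative shifts are rejected (interventions only add
activity in v1). Lagged response: the effective PIF at year t is the
unweighted mean of annual PIFs over inclusive offsets 0–5
(cardio-metabolic; 6 terms) or 10–30 (cancers; 21 terms), zero-padded
before the intervention start. Equal weights across the window are a
declared choice; a constant PIF series is invariant to the weighting.

**Adherence convention.** The default folds adherence into the affected
fraction (affected = awareness × download × use × adherence ≈ 0.58% of
eligible adults, receiving the full 285 MET-min effect). The alternative
reading — 285 × adherence applied to the larger
awareness × download × use group — is available via
`adherence_mode="effect"`; at these magnitudes the PIF is nearly linear
in (fraction × effect), so the two agree to first order.

## Synthetic data generator

The generator emulates the statistical structure the MSLT needs, not any
real dataset:

- **Demography.** 4.4 M people, 15% indigenous, a broadly flat-then-
  declining age pyramid (indigenous group skewed younger). Mortality is
  Gompertz–Makeham, μ(a) = 5×10⁻⁴ + 3×10⁻⁵·e^{0.095a}, with
  multiplicative stratum factors (male ×1.2, indigenous ×1.5), so q(a)
  is strictly increasing beyond age 35 and indigenous mortality is never
  below the reference group. pYLD(a) = 0.03 + 0.22(a/110)² (indigenous
  ×1.2).
- **Disease epidemiology.** Exponential-in-age incidence from a
  disease-specific onset age, age-rising case fatality, flat remission
  for cancers only, breast cancer restricted to female strata, and mild
  seeded stratum jitter. A cell-by-cell audit confirms the implied
  disease mortality (period prevalence × case fatality) never exceeds
  all-cause mortality; violations trigger damped (×0.7) regeneration and
  eventually an error.
- **Exposure.** A zero-inflated lognormal (10% fully inactive, σ = 1)
  per sex × ethnicity × adult 5-year band, binned as above. Each
  stratum's location parameter is solved by bounded root-finding so the
  fraction below 450 MET-min/week (150 guideline minutes at MET 3.0)
  equals 42% ± a small seeded jitter; the population-weighted adult
  share lands at ~42% insufficiently active.
- **Costs.** Per-disease phase costs (first year, subsequent year, last
  six months of life, the latter attached to disease-cause deaths in the
  year of death) with the constraint last-6-months ≥ subsequent-year;
  per-capita unrelated annual cost 1400·e^{0.022a} NZ$.

Identical (spec, scenario) inputs produce byte-identical CSV tables;
every table carries a schema-version header line. What the generator
does **not** emulate: real age pyramids or survey microdata, correlation
between activity and disease risk beyond the RR curve, secular trends in
rates, competing non-modelled causes with activity associations, or
measured dose–response magnitudes. Passing tests therefore demonstrate
the correctness and internal consistency of the machinery, not the
external validity of any particular QALY or ICER figure.

## Costing and CEA conventions

Net cost = campaign cost (year 0, undiscounted by the base-year
convention) + disease cost offsets + unrelated costs, each discounted at
Σ vₜ/(1+r)^t. Unrelated costs apply only to *incremental* life years —
that is what makes them appear in the BAU-vs-intervention net. Subgroup
ICERs spread the campaign cost evenly over the eligible baseline
population. ICER quadrants: gains with positive net cost give the plain
ratio; "cost-saving" flags the dominant quadrant; "dominated" the
opposite; zero QALY change yields an undefined-ICER flag rather than a
division. Currency is 2011 NZ$ throughout.

The **equity adjustment** replaces the indigenous strata's main-table
mortality and pYLD with same-sex, same-age reference-group values while
leaving disease epidemiology, exposure, and intervention parameters
untouched; with the synthetic mortality multiplier above 1 this strictly
raises indigenous per-1000 QALY gains and leaves the reference group
bit-identical.

## Uncertainty analysis

The six intervention parameters are sampled independently: betas for the
four pathway proportions, fitted to (central, 95% interval) triples by
pinning the mean and solving the concentration so the 2.5%/97.5%
quantiles match in least squares (achieved quantiles are stored; with
the mean pinned, a strongly asymmetric interval can only be matched to
~0.01–0.015); a normal (285, 43) truncated at zero by resampling for the
effect size; a gamma with mean 2,883,000 and SD 20% of the mean for the
cost. One RNG substream is spawned per run from the master seed, so
results are independent of execution order and stable under increasing
run counts.

The CEAC counts a run as cost-effective at threshold λ iff its net
monetary benefit λ·ΔQALY − Δcost is non-negative — coherent where the
raw "ICER < λ" rule breaks for negative ICERs. The curve is
non-decreasing in λ whenever no run loses health, which the model
guarantees (protective RRs, non-negative shifts). Tornado analysis moves
one parameter at a time to its 2.5th/97.5th percentile and sorts by ICER
range width; with the default distributions the cost parameter dominates
the net-cost bars and the app-use parameter (the widest relative
interval) dominates the QALY bars.

Point-mass distributions reproduce the deterministic expected-value run
exactly, which is also the mode used for the scenario table (base,
40–79 targeting, 5-year maintenance, 0%/6% discount).

## Problem sizes and tolerances

Default runs simulate the full 110-cohort × 110-year grid for 4 strata
and 5 diseases (a run takes ~0.1 s; Monte Carlo reuses the cached BAU).
The test suite verifies: PIFs against a brute-force expected-risk sum to
1e-12 on randomized distributions; disease-table proportions against
exhaustive Markov matrix powering to 1e-12; toy-cohort QALY totals
against a seeded 10⁶-individual microsimulation within 3 Monte Carlo
standard errors (morbidity and mortality feedback channels tested
separately — with both active, the individual-level process differs from
the proportional cohort product by O(dw·π·f) through the within-year
correlation between death and the disease state in the QALY weight,
an inherent approximation of this model class); state conservation to
1e-10; and the accounting identity net = campaign + offsets + unrelated
to 1e-6 relative. The acceptance script uses 200 Monte Carlo runs for
its summary statistics, a deliberately scaled-down analogue of the
2000-run convention for this model family.

## Known limitations

- Proportional-hazards independence between disease tables and the main
  table (quantified above on the toy instance).
- No diabetes→CHD/stroke risk linkage, no respiratory or injury
  pathways, no repeat campaigns, no societal/productivity perspective.
- Synthetic RR magnitudes and cost levels are placeholders; absolute
  QALY/ICER outputs characterise the synthetic world only.
- One-dimensional exposure; no nonlinear (e.g. square-root)
  dose–response option in v1.
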