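# pamslt

Proportional multistate life table (MSLT) modelling of population
physical-activity interventions: lifetime health gains in
quality-adjusted life years (QALYs), health-system cost impacts, and
cost-effectiveness, with full probabilistic uncertainty analysis.

The packaged application is a one-off national mass-media campaign that
promotes high-quality physical-activity smartphone apps to adults aged
15–79. The campaign pathway is a product of four proportions — awareness
(77.9%), app download (31%), app use for at least 7 days (16%), and
weighted annual adherence (15%) — and those reached gain 285 MVPA
MET-minutes of activity per week (≈1.6 h of brisk walking) for one year.
The campaign costs NZ$2,883,000, incurred in year 0. All epidemiological
and costing inputs come from a deterministic **synthetic-data
generator** (a stand-in for national survey, burden-of-disease, and
costing data), so every stage runs fully offline and reproducibly.

## The model

A closed population, stratified by sex and ethnicity ("indigenous" with
elevated background rates vs "other") and by single year of age at
baseline, is advanced annually until extinction at age 110 under
business-as-usual (BAU) and under the intervention:

- **Main life table** per stratum: all-cause mortality *q(a)* and a
  morbidity weight *pYLD(a)*; QALYs accrue as *L(a)·(1 − pYLD(a))*.
- **Parallel disease life tables** for five activity-related diseases
  (CHD, stroke, type 2 diabetes, colorectal cancer, breast cancer
  [females only]) with states {never-had/cured, prevalent, dead}; annual
  transitions use incidence *i*, case fatality *f*, and remission *r*
  (cancers only).
- **Exposure → incidence.** Weekly MVPA MET-minutes follow a binned
  population distribution. The intervention shifts the affected fraction
  of each bin up by the effect size; combined with log-linear protective
  relative risks *RR(e)* this gives a population impact fraction per
  year,

  PIF = (Σᵢ pᵢRRᵢ − Σᵢ p′ᵢRRᵢ) / Σᵢ pᵢRRᵢ,

  which scales disease incidence as *i·(1 − PIF)*. Effects are lagged:
  the effective PIF in year *t* averages annual PIFs over the past 0–5
  years (cardio-metabolic) or 10–30 years (cancers).
- **Feedback.** Intervention-vs-BAU differences in disease mortality and
  prevalence adjust the main table's all-cause mortality and pYLD.
- **Costing.** Net cost = campaign cost + disease cost offsets (phase
  costs for the first year, subsequent years, and last six months of
  life) + unrelated health-system costs on incremental life years. Both
  QALYs and costs are discounted at 3% (0%/6% as scenarios);
  ICER = net cost / QALY gain.
- **Uncertainty.** The six intervention parameters carry beta / truncated
  normal / gamma distributions; Monte Carlo runs summarise the 50th
  (2.5th–97.5th) percentiles, a cost-effectiveness acceptability curve
  (net-monetary-benefit rule), and tornado diagrams.

## Worked example

```python
from pamslt import generate_inputs, prepare_bundle, InterventionSpec

inputs = generate_inputs()            # synthetic world, seed 0
bundle = prepare_bundle(inputs)       # caches the BAU run
result = bundle.run(InterventionSpec())
print(round(result.qaly_gain, 3), round(result.net_cost), round(result.icer))
```

prints

```
6.269 2841124 453189
```

i.e. under the default synthetic scenario the campaign gains **6.27
QALYs** (≈0.0014 per 1000 population) over the remaining lifetime of a
4.4-million population, at a **net cost of NZ$2,841,124** (campaign cost
NZ$2,883,000 minus NZ$75,604 of disease cost offsets plus NZ$33,728 of
unrelated costs), an **ICER of NZ$453,189 per QALY**. Maintaining the
activity increase for 5 years instead of 1 raises the gain to ~29.9
QALYs and cuts the ICER to ~NZ$89,000. These magnitudes are properties
of the synthetic world; the qualitative structure (small gains, cost
per QALY far above typical thresholds, strong sensitivity to effect
maintenance) is what the model family is designed to expose.

The same pipeline is scriptable from the shell:

```bash
pamslt all --seed 0 --out-dir out --n 2000
```

## Layout

- `pamslt.synth` — synthetic population, disease, exposure, cost, RR generator (CSV in/out)
- `pamslt.exposure` — unit conversions, distribution shifts, PIFs, lags
- `pamslt.lifetable` — the MSLT engine (main + parallel disease tables)
- `pamslt.intervention` — campaign pathway, counterfactual exposures, cost stream
- `pamslt.cea` — cost offsets, unrelated costs, ICER, equity adjustment
- `pamslt.uncertainty` — parameter distributions, PSA, CEAC, tornado
- `pamslt.pipeline` / `pamslt.cli` — orchestration, reports, `pamslt` console script

See `docs/methods.md` for modelling assumptions, parameter defaults, and
known limitations.
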