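# shs-hia

Dynamic health impact assessment (HIA) of second-hand smoke (SHS) exposure:
projection of ischaemic heart disease (IHD), chronic obstructive pulmonary
disease (COPD) and stroke morbidity attributable to SHS in an ageing
population, and comparison of exposure-reduction policy scenarios against a
never-exposed counterfactual.

The package is aimed at epidemiologists and public-health modellers who
want a transparent, fully testable implementation of the multistate
Markov / partial micro-simulation approach used in national SHS burden
assessments: population-level disease inputs, risk back-calculation from
relative risks, individual exposure histories, and prevalence projections
over a multi-decade horizon.

## The model

**Risk factor.** SHS exposure is a two-state categorical risk factor
(exposed / unexposed).  A cross-sectional exposure prevalence profile
p(s, a) by sex and age group is expanded to single years of age and
converted to annual net transition probabilities that reproduce the
profile exactly when a cohort is propagated through them.

**Back-calculation.** Disease inputs (prevalence, incidence, excess
mortality) are supplied at the population level only.  Given the relative
risk RR of disease for exposed versus unexposed people, the stratum rates
are the unique solution of

    (1 − p)·r_u + p·r_e = r_total,      r_e = RR · r_u
    ⇒  r_u = r_total / (1 − p + p·RR)

The population attributable fraction follows as

    PAF = p(RR − 1) / (1 + p(RR − 1)) = 1 − r_u / r_total.

**Partial micro-simulation.** Exposure histories are simulated as hard,
randomly drawn individual states (micro); disease occupancy is carried per
individual as a probability (macro).  For one disease the annual update of
the diseased share q at age a is

    q' = [ q·(1−qb)·(1−qx) + (1−q)·(1−qb)·i ] / [ q·(1−qb)·(1−qx) + (1−q)·(1−qb) ]

with incidence i chosen from the exposed or unexposed stratum according to
the individual's current state, excess mortality qx on prevalent cases and
background (other-cause) mortality qb.  Diseases are chronic (no
remission) and conditionally independent given age, sex and the exposure
history; the joint distribution over the 2³ disease combinations is the
product of the marginals.  A deterministic engine mode propagates the
exact 4-state (exposure × disease) chain per cohort and equals the
expectation of the micro mode — it serves as the noise-free reference.

**Demography.** One-year ages to an open-ended 95+ bucket, all-cause
mortality per sex and age, constant newborn inflow at a male:female sex
ratio of 1.05, no migration.

**Scenarios.** From a start year the exposure targets are scaled by
(1 − success rate) — 0% (reference), 20%, 100% (eradication) — with the
required share of exposed individuals moved to the unexposed state at that
instant.  Attributable cases in any year are scenario-world cases minus
the cases of a world in which SHS never existed (all-unexposed rates).

## Worked example

The national disease and population files behind the published German
assessment are not public, so runs use a synthetic study fixture with the
same structure (ageing pyramid, late-onset chronic disease curves, the
published exposure and relative-risk tables), scaled to one million
people:

```python
from shs_hia import HIAModel, generate_full_study_fixture

fx = generate_full_study_fixture(seed=1)
model = HIAModel(fx.population, fx.disease_inputs, fx.exposure, fx.rr, fx.config)
res = model.run()
print(res.summary())
```

```
Dynamic HIA of second-hand smoke exposure
horizon 2014-2040, engine=micro, n_individuals=10000, seed=1
attributable prevalent cases (n) and attributable population prevalence (% of same-sex population):
   scenario  year  ihd_male_n  ihd_male_pct  ihd_female_n  ihd_female_pct  copd_male_n  copd_male_pct  copd_female_n  copd_female_pct  stroke_male_n  stroke_male_pct  stroke_female_n  stroke_female_pct
  reference  2014         171          0.03           560            0.11          685           0.14            719             0.14            430             0.09              306               0.06
  reference  2040         221          0.04           728            0.14          860           0.17            886             0.17            554             0.11              387               0.08
success_100  2014         171          0.03           560            0.11          685           0.14            719             0.14            430             0.09              306               0.06
success_100  2040          10          0.00            43            0.01           15           0.00             21             0.00             16             0.00               12               0.00
 success_20  2014         171          0.03           560            0.11          685           0.14            719             0.14            430             0.09              306               0.06
 success_20  2040         181          0.04           590            0.12          700           0.14            710             0.14            451             0.09              311               0.06
```

Reading the table: in this one-million-person synthetic world the
reference scenario carries 685 male COPD cases attributable to SHS in
2014 (0.14% of all men), rising to 860 by 2040 purely through population
ageing — inputs are held constant, so the increase is demographic.  All
three scenarios coincide in 2014 (an intervention cannot erase prevalent
cases instantly).  By 2040 eradication removes
`res.scenario_reduction(scenario="success_100", year=2040)` → **96.8%**
of the attributable burden (only pre-2014 cases linger), while the 20%
scenario removes **19.1%**, leaving 2040 roughly at the 2014 level.

The published German worked example ships with the package; its derived
headline statistics are recomputed from the printed table by the same
aggregation operations:

```python
from shs_hia import germany
germany.derived_statistics()["ihd_attributable_cases_2014"]   # 687254.0
germany.derived_statistics()["male_stroke_attributable_share_pct"]  # 28.03
```

A command-line interface wraps the library: `hia synth --seed 3 --out d/`
generates a fixture, `hia run --config d/config.yaml` runs it, and
`hia report --results d/results` prints the summary table.

## Layout

| module | contents |
| --- | --- |
| `shs_hia.model_io` | domain types, CSV schemas, YAML run configuration |
| `shs_hia.epi_core` | mixture back-calculation, PAF, counterfactual rates |
| `shs_hia.riskfactor_dynamics` | age-group expansion, net transitions, scenarios, exposure histories |
| `shs_hia.disease_engine` | disease-occupancy updates, joint distribution, demography, both engine modes |
| `shs_hia.scenario_reporting` | scenario execution, aggregation, report tables, plots |
| `shs_hia.synthetic_data` | synthetic population / disease-input generator |
| `shs_hia.germany` | published German tables (worked-example inputs) |
| `shs_hia.hia` | `HIAModel` / `HIAResults` front end |
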