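# Methods

## Model structure

The model is a discrete-time (one-year) multistate Markov model of three
chronic diseases — ischaemic heart disease, COPD and stroke — under a
two-state categorical risk factor, exposure to second-hand smoke (SHS).
The state space per individual is (age, sex, exposure state, disease
status per disease, alive).  Its assumptions:

* **Chronic, no remission.** Once diseased, always diseased; disease can
  only end in death.
* **One relative risk per sex and disease.** Effect sizes do not vary
  with age; exposure raises prevalence and incidence by the same RR
  (the evidence base provides no separate prevalence/incidence RRs).
* **Conditional independence of diseases** given age, sex and the
  exposure history.  The joint distribution over the 2³ disease
  combinations is the product of the marginals; no cross-disease risks
  are modelled because none are available.
* **Exposure dynamics are autonomous**: disease states never influence
  exposure transitions.
* **Demography without migration.** One-year ages 0–94 plus an open-ended
  95+ bucket; constant annual newborn inflow split male:female 1.05:1.

### Back-calculation

Disease inputs are population-level.  With exposed fraction p and
relative risk RR, stratum rates are the unique solution of the mixture
identity (1−p)·r_u + p·r_e = r and r_e = RR·r_u, i.e.
r_u = r / (1 − p + p·RR).  Both prevalence and incidence are split this
way; excess mortality is not exposure-specific.  The split is validated
to stay in [0, 1] and recombines to the population rate to machine
precision.  The attributable fraction implied at baseline is the
classical PAF p(RR−1)/(1+p(RR−1)); it is exact in the deterministic
engine at the start year (verified to 1e-10 in the tests) and is
bounded above by 1 but unbounded below for protective exposures.

### Exposure dynamics

The grouped exposure profile is expanded piecewise-constant to single
years (ages below 18 carry zero exposure — no data exist for minors) and
converted to one-sided **net** annual transition probabilities: a falling
profile needs only outflow (p(a)−p(a+1))/p(a), a rising one only inflow
(p(a+1)−p(a))/(1−p(a)).  The two-flow problem is underdetermined from
cross-sectional data; net flows are the minimal solution and reproduce
the target profile exactly (tested to 1e-12).  Individual histories are
sampled from these probabilities with one seeded generator per run;
draws are vectorised year-major over all individuals, which keeps runs
bit-reproducible under the seed.

### Annual cycle and timing

All rates are **annual risks** (probabilities), not instantaneous
hazards: the inputs of national HIA tools are tabulated this way and the
one-year update composes them multiplicatively.  A year lived at age a in
exposure state e contributes, per disease,

    diseased:  q → q·(1−qb(a))·(1−qx(a))  plus onsets (1−q)·(1−qb(a))·i_e(a)
    healthy:   (1−q) → (1−q)·(1−qb(a))·(1−i_e(a))

followed by the exposure transition at source age a and the age shift
a → a+1 (the 95+ bucket feeds back into itself).  Charging rates at the
*source* age is the standard life-table convention and matches the
population projection, so numerator (cases) and denominator (population)
survive identically when excess mortality is zero.  The prevalent-share
update is algebraically invariant to background mortality (it cancels in
the ratio); background mortality matters only for the unnormalised
person-masses that become case counts.

**Background mortality** is other-cause mortality,
qb = q_all − Σ_d prev_d·qx_d (clamped at 0): the all-cause input already
contains the deaths of prevalent cases, and subtracting the
prevalence-weighted excess avoids charging them twice.

### Partial micro-simulation and its deterministic twin

Exposure histories are sampled per individual (micro); disease occupancy
is a per-individual probability mass (macro).  Because the disease masses
evolve *linearly* given an exposure path, the expectation over paths is
itself a Markov chain on {unexposed, exposed} × {healthy, diseased}; the
deterministic engine mode propagates that 4-state chain per (sex, cohort,
disease) and is the exact expectation of the micro mode, cell for cell.
The tests verify this against an independent brute-force enumeration of
exposure paths (to 1e-12 for the deterministic mode; within three
binomial standard errors for the sampled mode).

In micro mode the configured sample size (default 10,000, the study's
design choice: a categorical risk factor needs only a small
representative sample) is divided equally over all populated (sex,
baseline-age) cohorts; each simulated individual carries the weight
cohort population / per-cohort sample.  Newborn cohorts entering after
the start year get the same per-cohort sample size.  All scenarios replay
a common random-number stream, so the baseline year coincides exactly
across scenarios and scenario contrasts are comonotonically coupled.

### Scenarios and attribution

A scenario scales the exposure targets by (1 − success rate) from its
start year, as a single permanent shift: at that instant the required
fraction of currently exposed individuals moves to the unexposed state
(their accumulated disease probability moves with them), and transitions
re-derived from the scaled profile sustain the new targets.  Disease
occupancy at the start year is initialised from the back-calculated
stratum prevalence of each individual's *current* exposure state — the
pre-intervention history in compressed form; mixed histories before the
start year are not reconstructed.

Attributable cases in year t are scenario-world cases minus the cases of
a never-exposed counterfactual world (everyone on unexposed rates).  The
counterfactual contains no randomness and is always computed
deterministically, which keeps attributable estimates free of
counterfactual sampling noise.  The headline counts are prevalent cases
(disease-state occupancy); the reported percentage is the attributable
population prevalence, 100 · attributable cases / population.

## Parameters

| parameter | default | unit | rationale |
| --- | --- | --- | --- |
| horizon | 2014–2040 | years | 26-year projection window of the assessment design |
| n_individuals | 10,000 | persons | small representative sample suffices for a categorical risk factor |
| scenarios | 0% / 20% / 100% | success rate | reference, conservative post-ban reduction, eradication |
| newborn sex ratio | 1.05 | male per female | demographic convention |
| newborns per year | age-0 count | persons | stationary inflow absent a birth schedule |
| engine_mode | micro | — | the original tool's method; `deterministic` is the exact expectation |

Synthetic-fixture parameters (see `FixtureSpec`): total population 10⁶;
Gompertz all-cause mortality (coefficient 4.0e-5 men / 2.2e-5 women, rate
0.095 per year, base 2.0e-4) giving a realistic female survival advantage
at old age; logistic prevalence curves with onset ages 36 (IHD, stroke)
and 40 (COPD), levels 0.28 / 0.10 / 0.12, female scaling 0.55 / 0.65 /
0.85, and a COPD post-peak decline of 2.5%/year after age 79; excess
mortality ramps (1→6%, 2→12%, 2→10% per year over the age span).  These
were chosen once as plausible magnitudes for a Western European
population with late-onset chronic disease; incidence is then back-solved
so the profile is exactly stationary under the engine's own update, which
is what makes analytic results (PAF recovery, prevalence reproduction)
checkable.

## What the synthetic generator does and does not emulate

It reproduces the *structural* features the method relies on: an ageing
pyramid with a female surplus at high ages, diseases absent before the
mid-30s and rising steeply with age, male prevalence above female, a
non-monotone COPD profile, and internally consistent
prevalence/incidence/excess-mortality triples.  It does **not** reproduce
the absolute German magnitudes (the national disease files are not
public), secular trends in incidence or exposure, competing risk factors,
regional legislation differences, or uncertainty in the relative risks
(point estimates only, by design).  Passing tests therefore demonstrate
the correctness of the machinery — back-calculation, propagation,
attribution, aggregation — not the realism of any particular national
figure.

Two consequences are worth noting when comparing with the published
German numbers.  First, with the published male IHD relative risk of
1.06, the male IHD PAF is necessarily small (≈1–4%), so in the synthetic
world attributable IHD counts are *higher* in women (RR 1.50) — the
published table's reverse pattern cannot be derived from its own printed
inputs and rests on the unpublished national files.  Second, eradication
removes ≈97% of the synthetic attributable burden by 2040 (only pre-2014
cases linger), not the published 50%; the halving in the published table
follows an accounting that its description does not specify, so the
engine is not forced to reproduce it — the published 50% figure is
verified as table arithmetic, the engine's own value is reported
separately.

## Numerical choices

* Proportions are validated to [0, 1] at parse time; relative risks must
  be finite and positive; splits that would push a stratum probability
  above 1 raise an error naming the stratum.
* If every member of a stratum dies in a year, the updated disease share
  is defined as 0 (the mass is 0 anyway).
* A profile that falls away from zero exposure raises (no outflow can
  produce it); constant profiles need no transitions.
* Back-solved incidence must lie in [0, 1]; a prevalence decline steeper
  than excess mortality can explain raises at generation time.
* Report percentages are rounded half away from zero at presentation
  only (one decimal for percent changes, two for shares); internal
  values keep full precision.
* Tolerances: algebraic identities (mixture, joint-distribution
  normalisation, profile propagation, deterministic-vs-enumeration) are
  asserted at 1e-9–1e-12; sampled quantities at three Monte-Carlo
  standard errors, aggregated to (sex, disease, 10-year age band) strata
  so the 3σ criterion keeps its nominal error rate over the number of
  comparisons made.

## Problem sizes

The default test and reproduction runs use the full 2014–2040 horizon
with a one-million-person synthetic population and 10,000 simulated
individuals (the study's own sample size); the micro/deterministic
equivalence check uses a one-cohort toy world at n = 100,000 where all
eight exposure paths can be enumerated exactly.  A complete three-scenario
run takes well under a second.

## Known limitations

* Initialisation from the current exposure state at baseline understates
  the heterogeneity of pre-baseline exposure histories; the original
  tool's treatment of this is not documented and may differ.
* Excess mortality is additive on background mortality and shared across
  exposure strata; no exposure-specific case fatality.
* No migration, no secular trends, no age-varying relative risks, no
  uncertainty propagation from the published confidence intervals.
* Disease-specific survival differences mean case masses and the
  population pyramid use slightly different survival above the first
  order in (q·qx); the discrepancy vanishes when excess mortality is
  zero and is negligible at realistic magnitudes.
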