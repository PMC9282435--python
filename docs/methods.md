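# Methods

## The model

`obesim` simulates a national population one calendar year at a time from
2020 to 2040. Each simulated person has a sex, a birth year, a fixed BMI
percentile rank, a set of disease states with onset years, a death
year/cause, and accrued costs. Within a year, events happen in a fixed
order:

1. **Vital update** — every alive individual dies with the background
   all-cause probability for its (sex, single-year age); newborns enter at
   age 0 via one Bernoulli trial per alive woman at her age-specific
   fertility rate (50:50 sex ratio). Deaths are flagged, never removed, so
   cumulative tallies persist.
2. **BMI category assignment** — rank-quantile against the projected
   category probabilities for the individual's (sex, age band, year).
3. **Disease contraction** — independent Bernoulli first-onset draws per
   disease at the individual's per-category annual probability; diseases
   are absorbing (no remission).
4. **Disease deaths** — chronic liver disease and liver cancer kill
   prevalent cases with a per-case annual probability; T2DM carries no
   excess mortality.
5. **Cost accrual and end-of-year tallies.**

Single-year ages 0–100 are simulated internally so cohorts flow into the
20–59 reporting window over the horizon; results are tallied in five-year
bands for ages 20–59 and rescaled to the projected national population by
per-(year, sex, band) weights `projected / simulated`. The population is
closed apart from births and deaths (no migration).

## BMI-category trends

Cross-sectional surveys give the shares of healthy weight (<25 kg/m²),
pre-obesity (25–29.99) and obesity (≥30) per sex and age band at a handful
of years, with sample sizes. Per stratum we maximise the sample-size-weighted
multinomial likelihood of a softmax model with healthy weight as reference.
Two time parameterisations of the non-reference log-odds η_c are available:

- **linear** (2 parameters per category): η_c(t) = a_c + b_c (t − 2010).
  Identifiable from two distinct survey years; with exactly two the fit is
  saturated and interpolates the data.
- **saturating** (default; 2 per category + one shared rate): η_c(t) =
  a_c + b_c (1 − e^{−k(t−2010)})/k, k > 0. Reduces to the linear form as
  k → 0 and levels off at a_c + b_c/k, so a steep recent rise cannot
  extrapolate without bound over 20 years. Needs three distinct years. The
  published description of the original model names only a "non-linear
  categorical regression"; both forms here are reconstructions and the
  choice is a config switch.

Numerical choices: the optimiser is initialised from a weighted least
squares fit to the observed log-odds (clamped to the floor); the linear form
uses the analytic gradient with BFGS and reports Wald slope intervals from
the analytic observed information; the saturating form uses Nelder–Mead.
A category observed identically at zero is pinned at the log-odds floor
(default −20, slope 0) with a warning; all projected log-odds are clipped to
[floor, −floor], and probabilities always sum to 1 by the softmax
construction. Loaders tolerate missing (year × stratum) cells, e.g. a survey
wave that excluded older respondents. A reporting band with no fitted
stratum borrows the nearest fitted band of the same sex; individuals older
than the surveyed range keep the oldest band's mix, children count as
healthy.

**Rank preservation.** Each individual's percentile rank is fixed for life;
assignment is monotone in rank, so as marginal probabilities drift an
individual crosses category boundaries smoothly and never leapfrogs. This is
the minimal longitudinal-persistence assumption consistent with
cross-sectional inputs, and it makes the population's category shares match
the marginals exactly in expectation.

**Counterfactual.** The zero-obesity scenario maps every probability vector
to (1, 0, 0): all individuals are healthy-weight in every year. Everything
else — demographics, hazards, random draws — is unchanged.

## Disease model

Inputs are overall incidence (all three diseases), prevalence and mortality
(chronic liver disease), and mortality (liver cancer) per (sex, age band),
accepted per 100,000 or per person-year with an explicit units column, plus
relative risks per BMI category with healthy weight ≡ 1. Literature odds
ratios are used directly as RRs under the rare-disease assumption
(incidence below 10%).

- **Partition**: λ_healthy = I/(p·rr), λ_c = rr_c λ_healthy, where p is the
  *baseline* category distribution for that stratum-year. The identity
  Σ p_c λ_c = I holds to machine precision, keeping the simulated
  population-average incidence calibrated to the source rates; the
  counterfactual reuses the baseline partition (it changes who is exposed,
  not the per-category hazard). Any other decomposition would decalibrate
  the baseline from its inputs.
- **Rate → risk**: annual probability 1 − e^{−λ} (constant hazard within a
  year).
- **Case fatality**: chronic liver disease uses mortality/prevalence as the
  death hazard among prevalent cases. Liver cancer has no prevalence input;
  its prevalent pool is approximated as incidence × mean survival (default
  1 year, configurable), giving a high per-case fatality consistent with a
  rapidly fatal cancer. Cases that survive the draw stay prevalent.
- Rates are held at their source-year values across the horizon; only the
  BMI-category distribution evolves. Background all-cause mortality is used
  as given (disease deaths are additive, not netted out) — a documented
  simplification; it slightly double-counts liver-disease deaths already in
  the all-cause schedule, but those are ~1 per 100,000.
- No T2DM→liver-disease pathway and no fibrosis stage structure: chronic
  liver disease is a single state. Stage-level transition rates are not
  available in the source material; modelling them would be invention.

## Scenario pairing, replication and error

Uniform variates are keyed by (replicate seed, year, purpose) and indexed by
individual id, so the baseline and counterfactual runs of one replicate
consume identical randomness (common random numbers; switchable off). Under
CRN and rr ≥ 1 the counterfactual's contraction probability is never above
the baseline's for the same individual-year, so attributable incidence is
non-negative per replicate up to a second-order path: an individual who dies
of liver disease in the baseline but survives in the counterfactual can
later contract a disease there. At realistic rates this affects ≪1 case per
replicate and cannot flip disease-level totals.

Replicates are independent seeds spawned from the master seed. Every
reported cell keeps its full replicate stack, so any derived aggregate
(cumulative totals, combined diseases, sex totals) carries an honest
half-width 1.96·SD/√R computed on the aggregate itself. These half-widths
quantify Monte Carlo noise only — not sampling error in the inputs nor
parameter uncertainty — and are labelled accordingly, not as confidence
intervals.

Determinism: a fixed master seed yields bit-identical outputs on one
platform; generated input bundles are byte-identical per seed.

## Costing

Annual per-patient costs (defaults: 2,704.41 USD for T2DM, 8,923.62 USD for
chronic liver disease) accrue for every alive prevalent case-year starting
in the onset year; the liver-cancer cost (13,259.80 USD, defined over the
last 12 months of life) is charged once in the year of death from liver
cancer. Cases surviving the horizon never accrue it — conservative, since
the source cost is terminal by definition. No discounting or inflation
adjustment is applied; the currency-year label (2010 USD) is carried through
to outputs. Only cases arising within the simulation are costed; there is no
prevalent-at-baseline seeding, so early-horizon cost and prevalence levels
are below what a warmed-up population would show (the attributable
*difference* is much less affected, since baseline-seeded cases would appear
in both scenarios).

## Synthetic inputs

The generator emits the full input surface — pyramid, fertility, mortality,
projected population, surveys, rate and RR tables, cost constants — from a
`GroundTruth` parameter set, so every stage is testable with known answers.
Defaults: survey waves 2005/2011/2013/2016 with the 50+ strata absent from
2016; multinomial noise at sample size 2,000 per stratum (or the noiseless
limit); 2013 obesity anchored at 24.1% (men) and 33.5% (women) with log-odds
slopes +0.025/yr (men) and −0.005/yr (women); T2DM incidence rising from 300
to ~1,400 per 100,000 across 20–59; liver-disease rates 10.5 incident / 1.2
fatal / 500 prevalent per 100,000; Gompertz-like background mortality;
fertility 0.08/woman-year over ages 15–49; a male-surplus exponential
pyramid; and a 20–59 projected population of 34.81M in 2020 growing
1.5%/year. Default RRs (1, 3, 7) for T2DM, (1, 2, 5) for chronic liver
disease and (1, 1.5, 2) for liver cancer are plausible literature-scale
values supplied via config — the original RR magnitudes are cited, not
printed, in the source material.

What a green test does **not** establish: the synthetic world has no
migration, no secular change in disease rates, identical trends across age
bands, and stylised demographic schedules, so passing tests validate the
machinery and its calibration identities, not any real country's projection.
Reproducing published national headline numbers would require the actual
survey, registry, burden-of-disease and demographic tables plus ~10⁸
simulated individuals.

## Known limitations

- Annual resolution; no within-year event ordering beyond the fixed
  sequence above.
- Liver cancer counts in the 20–59 window are tiny; at desk scale their
  Monte Carlo half-widths can exceed the point estimates.
- Per-100k rates use the whole projected 20–59 population as denominator
  (not the disease-free population).
- Newborn random streams are positionally keyed, so scenario coupling decays
  for cohorts born after the scenarios' birth counts diverge; these cohorts
  are at most 20 years old by 2040 and contribute negligibly to outcomes.
- Costs for individuals who age past 59 stop being tallied (working-age
  reporting), though they continue to accrue on the individual.
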