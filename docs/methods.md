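# Methods

## The question the simulation answers

Two-source record linkage can be performed on a unique person identifier
(direct, DII) or on a composite of quasi-identifiers — name token, date of
birth, sex (indirect, III). The III join suffers missed matches (identifier
discrepancies between sources) and false matches (key collisions between
different people). `linklevel` generates cohorts where the truth is known,
realizes both linkage levels on the same corrupted sources, runs an
identical analysis battery on each, and classifies the agreement of the
results. Because the DII cohort is treated as the reference, every
discrepancy is attributable to the linkage-error process, which is fully
under the experimenter's control.

## Data-generating model

Each of five cancer strata (TC, GC, BC, PC, CC in decreasing default size)
is generated independently:

* **Identifiers.** `uid` is unique by construction. `name_key` is drawn
  from a finite dictionary (default 4,000 tokens), so homonyms arise
  naturally; `dob` is derived from age at diagnosis plus a uniform
  within-year offset, keeping age and date of birth coherent; sex is fixed
  by the disease for BC/CC (female) and PC (male).
* **Covariates.** Residence (urban 0.72), insurance type (employee 0.55 /
  local 0.40 / medical aid 0.05), premium quantile (0 reserved for medical
  aid, otherwise uniform on 1–10), Charlson comorbidity category
  (0–1 / 2 / 3 / ≥4 with probabilities 0.55/0.20/0.13/0.12), SEER summary
  stage per stratum. Age is normal per stratum (e.g. 48 ± 11 for TC,
  68 ± 8 for PC), truncated to 18–95.
* **Treatment.** A categorical arm per stratum (vitamin D for TC, surgery
  type for GC, hormone-therapy type for BC, androgen deprivation for PC,
  radiotherapy for CC) drawn from configured prevalences.
* **Outcome.** Inverse-CDF proportional-hazards sampling with an
  exponential baseline: `T = −log U / (λ e^{x'β})`, where β collects the
  per-arm true log hazard ratios and the covariate effects (default: 0.03
  per year of age over 55; 0 / 0.15 / 0.30 / 0.50 across CCI categories).
  Administrative censoring at 10 years; death and emigration are folded
  into censoring rather than modelled as competing risks. Event times are
  continuous, so ties only appear after external rounding. The fracture
  site is categorical among hip / vertebral / distal radius / proximal
  humerus, except in CC where the outcome is pelvic insufficiency fracture
  only.

Default true hazard ratios are anchored to the adjusted estimates reported
for these treatments in DII-linked national data (0.83, 1.26/1.40, 1.03 /
0.80 / 0.94, 1.96, 1.80). The default baseline hazards (0.010–0.014 per
person-year) are deliberately two to three orders of magnitude above the
absolute osteoporotic-fracture incidence seen in national data: at
simulation scale (tens of thousands of subjects rather than hundreds of
thousands) the realistic rates would produce almost no events. The package
therefore targets the *relative* structure (hazard ratios, error rates,
stratum size ordering), not absolute incidence; reported rates per 100,000
person-years are internally consistent but not calibrated to any
population.

## Error model

Each source record is subjected to three independent Bernoulli processes:

* **miss** (`miss_rate`, default 0.287): one III field is perturbed — a
  name-token swap or a date-of-birth edit — so the composite key no longer
  equals the partner's;
* **collision** (`collision_rate`, default 0.002): the record's III fields
  are overwritten with a *donor's* true values, engineering a false match.
  Donors are taken preferentially from records already slated for a miss
  (their own key is broken regardless); only when that pool is exhausted is
  a clean donor displaced. This keeps the realized false-match count
  proportional to `collision_rate` instead of depending on tie-rule luck,
  at the cost of a small (≈ one collision's worth) excess in the missed
  count;
* **DII miss** (`dii_miss_rate`, default 0.003): the unique identifier is
  blanked.

`informative_coeffs` maps pandas-query predicates to log-odds shifts
applied to the per-record miss probability through a logistic model,
enabling covariate- or outcome-dependent missingness (the mechanism behind
small-stratum bias). A base miss rate of exactly 0 or 1 is left unshifted.
Every change is logged (record, kind, field, old, new).

## Linkage

Linkage is deterministic exact-match on composite keys (`uid:<uid>` at
DII; `name|dob|sex` at III); probabilistic (Fellegi–Sunter) linkage is out
of scope. Records missing a key field are flagged unlinkable. Duplicate
keys within one source are resolved by keeping the earliest-index record
and reporting the rest in a collision report — deterministic and
auditable. Provenance (true vs false match) is assigned by comparing linked
record-id pairs against the truth sidecar, and the accounting identity
`n_linked = (n_total − n_missed) + n_false` holds exactly on every run.
Percentages are reported to one decimal.

## Analysis battery

* **Normality gate:** Shapiro–Wilk at α = 0.05 on each group, subsampled
  to at most 5,000 observations per group; groups with n < 3 fail the
  gate and route to the rank-based test.
* **Test selection:** continuous/2 groups → pooled two-sample t-test or
  Mann-Whitney; continuous/≥3 → one-way ANOVA or Kruskal-Wallis;
  categorical → Pearson chi-square unless more than 20% of expected cell
  frequencies are below 5, then Fisher's exact test. For tables larger
  than 2×2 the Fisher branch is a seeded Monte Carlo conditional test
  (20,000 tables with fixed margins via `scipy.stats.random_table`,
  ordered by the chi-square statistic), since no exact r×c implementation
  is available in the stack. All tests two-sided at 5%, no multiplicity
  correction.
* **Incidence:** exact (Garwood) Poisson intervals from chi-square
  quantiles: lower `qχ²(α/2; 2k)/2/PY` (0 when k = 0), upper
  `qχ²(1−α/2; 2k+2)/2/PY`, scaled per 100,000 person-years. Follow-up is
  measured in years of 365.25 days.
* **Cox fits:** lifelines `CoxPHFitter` (Efron tie handling — preferable
  to Breslow under the heavy ties a discretized time scale would create),
  Wald 95% intervals, reference arm reported as HR ≡ 1. The adjusted model
  uses all predeclared covariates except the treatment variable; subgroup
  fits exclude the stratifier. Non-convergence produces flagged estimates
  with diagnostics, never silent output. Model explanatory power is the
  partial-likelihood Cox–Snell pseudo-R², `1 − exp(2(ℓ₀ − ℓ₁)/n)`.
* **Stratum inclusion:** within each stratum the battery keeps only
  records whose treatment arm belongs to the stratum's protocol; a false
  match carrying another stratum's treatment label is thereby dropped as
  protocol-ineligible, mirroring real inclusion criteria.

## Concordance evaluation

Cohen's h (proportions) and Cohen's f (explanatory power) are standard.
Two conventions required a package-level decision:

* **Hazard-ratio pairs** are compared by mapping each HR to
  p = HR/(1+HR) and applying Cohen's h. The transform is symmetric, zero
  iff the HRs are equal, and yields the familiar printed magnitudes for
  near-equal HRs (≈0.01 for 1.24 vs 1.26). It is documented as a
  convention, not a claim about any external implementation, and some
  published cells computed with an unknown transform will not match it.
* **Incidence comparisons** use Cohen's h on per-subject event
  proportions, since no standard transform exists for rate pairs.

Interpretation bins are half-open with inclusive lower bounds: none
< 0.01 ≤ very small < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large. The verdict
decision table, evaluated top-down per paired comparison:

1. opposite directions and both CIs exclude the neutral value →
   insufficient (X);
2. effect ≥ 0.8 → insufficient (X);
3. 0.5 ≤ effect < 0.8 → poor (△);
4. opposite directions but not significantly so → poor (△);
5. otherwise → good (○).

"Similar estimates" in rule 5 is operationalized as effect < 0.5 with
agreeing directions; "significantly opposite" as point estimates on
opposite sides of the neutral value with both 95% CIs excluding it.
Classification uses unrounded effect sizes; display rounds to two
decimals. Descriptive/group-comparison proportions carry no effect
direction, so only rules 2/3/5 can fire for them. A grid cell aggregates
its comparisons by worst verdict; unpaired keys are reported as missing,
never dropped.

## Determinism and problem sizes

All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; a pipeline run is byte-identical given the
same config and seed (the manifest records SHA-256 checksums of every
artifact). The packaged experiments use scaled-down cohorts chosen to give
stable statistics at interactive run times: the reference scenario totals
53,500 subjects (scaled by `--scale`), parameter-recovery uses 200
replicates at n = 5,000, null calibration 1,000 replicates at n = 200, and
the informative-missingness bias experiment 100 replicates at n = 2,000.

## What the generator does and does not emulate

It emulates: five strata with realistic size ordering, stratum-specific
treatments and true hazard ratios, covariate distributions of the
claims-data type, quasi-identifier collisions from a finite name
dictionary, independent and informative linkage-error processes, and
administrative censoring. It does not emulate: real Korean name/RRN
formats, diagnosis- or prescription-code streams (comorbidity categories
are generated directly rather than derived from codes), competing risk of
death, time-varying treatment, propensity-score matching, or absolute
incidence levels. Passing tests therefore demonstrate the *mechanics and
direction* of linkage-error effects — power loss from missed matches,
attenuation/inflation from informative missingness, fragility of near-null
effects — not population-calibrated magnitudes.

## Known limitations

* Exact-match linkage only; no blocking, hashing or probabilistic scoring.
* The error model corrupts one source (claims); two-sided corruption can
  be composed manually but is not a config switch.
* Cohen's f is computed per model and reported, but cross-level verdicts
  rest on proportions and hazard ratios; explanatory-power concordance is
  informational.
* The Monte Carlo Fisher branch gives simulation-exact p-values
  (n = 20,000 tables), adequate for test selection studies but not for
  boundary-precision inference.
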