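# linklevel

**How much does the identifier level used for record linkage distort the
conclusions of an epidemiological study?**

When two administrative data sources — say, a national cancer registry and
health-insurance claims — are joined without a unique personal identifier,
the join has to rely on quasi-identifiers such as name, date of birth and
sex. Such *indirectly identifiable information* (III) linkage introduces
two error types: **missed matches** (the same person's records fail to
join, shrinking the cohort and the statistical power) and **false matches**
(two different people are joined, biasing associations). Linkage on a
unique identifier — *directly identifiable information* (DII) — is nearly
error-free but often legally unavailable.

`linklevel` is a simulation framework for quantifying the downstream impact
of that choice. It is aimed at epidemiologists and data-linkage units who
must decide whether III-linked data are good enough for a planned analysis.
The pipeline:

1. **simulates** paired registry and claims tables for five cancer strata
   of very different sizes (thyroid > gastric > breast > prostate >
   cervical), with covariates, a stratum-specific treatment and an
   osteoporotic-fracture outcome drawn from a proportional-hazards model
   (`T = −log U / (λ e^{x'β})`, exponential baseline, administrative
   censoring);
2. **corrupts** identifiers at configurable rates — a miss rate for
   quasi-identifier discrepancies, a collision rate for engineered key
   collisions and a miss rate for the unique identifier — optionally with
   *informative* (covariate- or outcome-dependent) missingness through a
   logistic model;
3. **links** the tables at both levels with deterministic composite-key
   equality and accounts for every error against the known truth;
4. **analyzes** both linked cohorts with the same battery: descriptive
   tables, rule-based group comparisons (t / Mann-Whitney / ANOVA /
   Kruskal-Wallis / chi-square / Fisher), person-years incidence with exact
   (Garwood) Poisson intervals, and simple/adjusted Cox proportional-hazards
   fits plus subgroup (moderation) fits;
5. **evaluates** concordance, treating the DII results as the gold
   standard: Cohen's *h* = |2 arcsin√p₁ − 2 arcsin√p₂| for proportions,
   Cohen's *f* = √(R²/(1−R²)) for model explanatory power, an arcsine map
   p = HR/(1+HR) for hazard-ratio pairs, effect-size bins (none < 0.01 ≤
   very small < 0.2 ≤ small < 0.5 ≤ medium < 0.8 ≤ large) and a three-tier
   verdict per analysis-by-stratum cell: **good (○)**, **poor (△)** or
   **insufficient (X)**.

## Worked example

```python
import linklevel as ll

cfg = ll.default_pipeline_config(scale=0.1, seed=5, output_dir="demo-run")
ll.run_pipeline(cfg, seed=5)
print(open("demo-run/linkage_flow.txt").read())
```

```
Linkage flow
============
[DII] truth pairs: 5,350
  linked:        5,336
  false matches: 0 (0.0%)
  missed:        14 (0.3%)
[III] truth pairs: 5,350
  linked:        3,800
  false matches: 9 (0.2%)
  missed:        1,559 (29.1%)
  linkage rate vs reference: 71.2%
```

At the reference error rates (28.7% III miss rate, 0.2% key-collision
rate, 0.3% DII miss rate) the III-linked cohort retains about 71% of the
DII-linked one — missed matches dominate, false matches stay rare. The
verdict grid (`demo-run/verdict_grid.txt`) summarizes what that does to
each analysis:

```
                       BC CC GC PC TC
analysis method
cox regression          △  ○  ○  ○  ○
descriptive statistics  ○  ○  ○  ○  ○
group comparison        ○  ○  ○  ○  ○
incidence rate          ○  ○  ○  ○  ○
subgroup analysis       ○  -  -  ○  -
legend: ○ = good, △ = poor, X = insufficient, - = not applicable
```

Most cells are good: with non-informative errors and adequate sample
sizes, III linkage mostly costs power, not validity. The breast-cancer Cox
cell is *poor* here because a near-null treatment HR flipped sides of 1
between levels (not significantly) — exactly the fragility small effects
have under linkage error. `demo-run/verdicts.json` carries the per-cell
detail, e.g. the cervical-cancer treatment effect:

```
HR(III) = 2.29  vs  HR(DII) = 2.18   effect size 0.02 ("very small") → ○
```

When missingness is made *outcome-and-arm-dependent* (control-arm fracture
records preferentially unlinkable), the III-level HR is biased upward in
essentially every replicate — see `ErrorModel.informative_coeffs` and the
bias experiment in `scripts/acceptance.py`.

The command line mirrors the library (`linklevel run | simulate | corrupt |
link | analyze | evaluate | report`); a fully explicit reference
configuration is checked in at `configs/default.yaml`.

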