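"""Statistical analysis battery for a linked cohort.

The same battery runs unchanged on cohorts linked at either identifier
level, so any difference between its outputs is attributable to linkage
error:

* descriptive summaries (mean ± SD, median (min, max), frequency (%)),
* two-or-more-group comparisons with rule-based test selection
  (t-test / Mann-Whitney / ANOVA / Kruskal-Wallis for continuous variables
  depending on a Shapiro-Wilk normality gate; chi-square / Fisher's exact
  for categorical variables depending on the expected-frequency rule),
* person-years incidence with exact (Garwood) Poisson intervals,
* simple and covariate-adjusted Cox proportional-hazards fits (Efron tie
  handling via lifelines) with Wald 95% intervals,
* stratified subgroup (moderation) fits.

All tests are two-sided at the 5% level; no multiplicity correction is
applied.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

ALPHA = 0.05
SHAPIRO_CAP = 5000  # per-group subsample ceiling for the normality gate


@dataclass
class GroupComparisonResult:
    variable: str
    groups: list[str]
    summaries: dict[str, str]
    test_used: str  # t-test | Mann-Whitney | ANOVA | Kruskal-Wallis | chi-square | Fisher
    statistic: float
    p_value: float


@dataclass
class IncidenceEstimate:
    events: int
    person_years: float
    rate: float
    ci_low: float
    ci_high: float
    per: float = 100_000.0
    ci_level: float = 0.95


@dataclass
class HazardRatioEstimate:
    term: str
    hr: float
    ci_low: float
    ci_high: float
    adjusted: bool
    covariates: list[str] = field(default_factory=list)
    reference_arm: str | None = None
    is_reference: bool = False
    converged: bool = True
    note: str = ""


@dataclass
class CoxFitResult:
    """One fitted proportional-hazards model plus fit-level diagnostics."""

    estimates: list[HazardRatioEstimate]
    n: int
    n_events: int
    log_likelihood: float
    log_likelihood_null: float

    @property
    def pseudo_r2(self) -> float:
        """Cox–Snell partial-likelihood pseudo-R²: 1 − exp(2(ℓ₀ − ℓ₁)/n)."""
        return float(1.0 - np.exp(2.0 * (self.log_likelihood_null - self.log_likelihood) / self.n))

    def estimate_for(self, term: str) -> HazardRatioEstimate:
        for e in self.estimates:
            if e.term == term:
                return e
        raise KeyError(term)


# ---------------------------------------------------------------------------
# descriptive statistics

def describe(cohort: pd.DataFrame, variables: list[str], strata: str | None = None) -> pd.DataFrame:
    """Descriptive table: continuous variables as n / mean ± SD / median (min,
    max); categoricals as frequency (percentage to one decimal)."""
    groups = [("all", cohort)] if strata is None else list(cohort.groupby(strata, observed=True))
    out = []
    for gname, gdf in groups:
        for var in variables:
            if var not in gdf.columns:
                raise KeyError(f"variable {var!r} not in cohort")
            col = gdf[var].dropna()
            if pd.api.types.is_numeric_dtype(col):
                if len(col) == 0:
                    out.append({"stratum": gname, "variable": var, "level": "", "summary": "empty", "flag": "empty"})
                    continue
                out.append({
                    "stratum": gname, "variable": var, "level": "",
                    "summary": (
                        f"n={len(col)}; {col.mean():.2f} ± {col.std(ddof=1) if len(col) > 1 else 0.0:.2f}; "
                        f"{col.median():g} ({col.min():g}, {col.max():g})"
                    ),
                    "flag": "",
                })
            else:
                n = len(col)
                counts = col.value_counts()
                if n == 0:
                    out.append({"stratum": gname, "variable": var, "level": "", "summary": "0 (0.0%)", "flag": "empty"})
                for level, cnt in counts.items():
                    out.append({
                        "stratum": gname, "variable": var, "level": str(level),
                        "summary": f"{cnt} ({100.0 * cnt / n:.1f}%)", "flag": "",
                    })
    return pd.DataFrame(out, columns=["stratum", "variable", "level", "summary", "flag"])


# ---------------------------------------------------------------------------
# group comparison with rule-based test selection

def _normality_ok(samples: list[np.ndarray], rng: np.random.Generator) -> bool:
    """Shapiro–Wilk gate at α=0.05 on each group (subsampled above the cap).

    Groups too small to test (n < 3) fail the gate, routing to the
    rank-based alternative.
    """
    for x in samples:
        if len(x) < 3 or np.ptp(x) == 0:
            return False
        if len(x) > SHAPIRO_CAP:
            x = rng.choice(x, size=SHAPIRO_CAP, replace=False)
        if stats.shapiro(x).pvalue < ALPHA:
            return False
    return True


def select_categorical_test(table: np.ndarray) -> str:
    """Chi-square unless > 20% of cells have expected frequency < 5."""
    expected = stats.contingency.expected_freq(table)
    if (expected < 5).mean() > 0.20:
        return "Fisher"
    return "chi-square"


def _fisher_rxc(table: np.ndarray, rng: np.random.Generator, n_sim: int = 20_000) -> tuple[float, float]:
    """Monte Carlo conditional test for r×c tables (margins fixed).

    scipy's exact Fisher test covers 2×2 only; larger tables use a seeded
    Monte Carlo over `scipy.stats.random_table` with the chi-square
    statistic as the ordering criterion.
    """
    chi_obs = stats.chi2_contingency(table, correction=False).statistic
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    sims = dist.rvs(n_sim, random_state=rng)
    exp = stats.contingency.expected_freq(table)
    with np.errstate(divide="ignore", invalid="ignore"):
        chi_sim = np.nansum((sims - exp) ** 2 / exp, axis=(1, 2))
    p = (1.0 + np.sum(chi_sim >= chi_obs - 1e-12)) / (n_sim + 1.0)
    return float(chi_obs), float(min(p, 1.0))


def compare_groups(
    cohort: pd.DataFrame,
    variable: str,
    group_var: str,
    seed: int = 0,
) -> GroupComparisonResult:
    """Compare ``variable`` across the levels of ``group_var``.

    Test selection follows fixed rules — continuous with 2 groups:
    t-test if every group passes the normality gate else Mann-Whitney;
    continuous with ≥3 groups: ANOVA else Kruskal-Wallis; categorical:
    chi-square unless >20% of expected cell frequencies are <5, then
    Fisher's exact test.  Two-sided, α = 0.05.
    """
    rng = np.random.default_rng(seed)
    sub = cohort[[variable, group_var]].dropna()
    levels = sorted(sub[group_var].unique(), key=str)
    if len(levels) < 2:
        raise ValueError(f"group variable {group_var!r} needs >= 2 non-empty levels")

    if pd.api.types.is_numeric_dtype(sub[variable]):
        samples = [sub.loc[sub[group_var] == g, variable].to_numpy(float) for g in levels]
        for g, x in zip(levels, samples):
            if len(x) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 observations for a continuous test")
        summaries = {
            str(g): f"{x.mean():.2f} ± {x.std(ddof=1):.2f}; {np.median(x):g} ({x.min():g}, {x.max():g})"
            for g, x in zip(levels, samples)
        }
        normal = _normality_ok(samples, rng)
        if _identical_samples(samples):
            test = ("t-test" if normal else "Mann-Whitney") if len(levels) == 2 else (
                "ANOVA" if normal else "Kruskal-Wallis")
            return GroupComparisonResult(variable, [str(g) for g in levels], summaries, test, 0.0, 1.0)
        if len(levels) == 2:
            if normal:
                res = stats.ttest_ind(*samples)
                test = "t-test"
            else:
                res = stats.mannwhitneyu(*samples, alternative="two-sided")
                test = "Mann-Whitney"
        else:
            if normal:
                res = stats.f_oneway(*samples)
                test = "ANOVA"
            else:
                res = stats.kruskal(*samples)
                test = "Kruskal-Wallis"
        return GroupComparisonResult(
            variable, [str(g) for g in levels], summaries, test,
            float(res.statistic), float(res.pvalue),
        )

    # categorical variable
    table = pd.crosstab(sub[variable], sub[group_var]).to_numpy()
    col_tot = table.sum(axis=0)
    summaries = {}
    ct = pd.crosstab(sub[variable], sub[group_var])
    for j, g in enumerate(ct.columns):
        summaries[str(g)] = "; ".join(
            f"{lvl}: {ct.iloc[i, j]} ({100.0 * ct.iloc[i, j] / col_tot[j]:.1f}%)"
            for i, lvl in enumerate(ct.index)
        )
    test = select_categorical_test(table)
    if test == "chi-square":
        res = stats.chi2_contingency(table, correction=False)
        stat, p = float(res.statistic), float(res.pvalue)
    elif table.shape == (2, 2):
        odds, p = stats.fisher_exact(table)
        stat, p = float(odds), float(p)
    else:
        stat, p = _fisher_rxc(table, rng)
    return GroupComparisonResult(variable, [str(g) for g in ct.columns], summaries, test, stat, p)


def _identical_samples(samples: list[np.ndarray]) -> bool:
    first = np.sort(samples[0])
    return all(len(x) == len(first) and np.array_equal(np.sort(x), first) for x in samples[1:])


# ---------------------------------------------------------------------------
# incidence

def incidence_rate(
    events: int,
    person_years: float,
    per: float = 100_000.0,
    ci_level: float = 0.95,
) -> IncidenceEstimate:
    """Incidence per ``per`` person-years with the exact (Garwood) Poisson CI.

    lower = qchisq(α/2; 2k)/2 / PY (0 when k = 0);
    upper = qchisq(1−α/2; 2k+2)/2 / PY; both scaled by ``per``.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    alpha = 1.0 - ci_level
    k = int(events)
    low = 0.0 if k == 0 else stats.chi2.ppf(alpha / 2.0, 2 * k) / 2.0
    high = stats.chi2.ppf(1.0 - alpha / 2.0, 2 * k + 2) / 2.0
    scale = per / person_years
    return IncidenceEstimate(
        events=k,
        person_years=float(person_years),
        rate=k * scale,
        ci_low=low * scale,
        ci_high=high * scale,
        per=per,
        ci_level=ci_level,
    )


# ---------------------------------------------------------------------------
# proportional-hazards fits

def _design(
    cohort: pd.DataFrame,
    treatment_var: str,
    covariates: list[str],
    reference_arm: str,
    duration_col: str,
    event_col: str,
) -> tuple[pd.DataFrame, list[str]]:
    df = pd.DataFrame(index=cohort.index)
    df["_T"] = cohort[duration_col].astype(float)
    df["_E"] = (cohort[event_col] == "fracture").astype(int) if cohort[event_col].dtype == object \
        else cohort[event_col].astype(int)
    arms = [a for a in sorted(cohort[treatment_var].astype(str).unique()) if a != reference_arm]
    treat_cols = []
    for arm in arms:
        col = f"{treatment_var}={arm}"
        df[col] = (cohort[treatment_var].astype(str) == arm).astype(float)
        treat_cols.append(col)
    for cov in covariates:
        if pd.api.types.is_numeric_dtype(cohort[cov]):
            df[cov] = cohort[cov].astype(float)
        else:
            levels = sorted(cohort[cov].astype(str).dropna().unique())
            for lvl in levels[1:]:  # first level is the reference
                df[f"{cov}={lvl}"] = (cohort[cov].astype(str) == lvl).astype(float)
    return df, treat_cols


def fit_cox(
    cohort: pd.DataFrame,
    treatment_var: str,
    covariates: list[str] | None = None,
    subset: pd.Series | None = None,
    reference_arm: str | None = None,
    duration_col: str = "event_time_years",
    event_col: str = "event_indicator",
) -> CoxFitResult:
    """Cox proportional-hazards fit returning Wald-interval hazard ratios.

    Empty ``covariates`` gives the simple (treatment-only) model; the
    adjusted model passes every predeclared covariate except the treatment
    variable itself.  Ties are handled with the Efron approximation.
    Non-convergence yields flagged estimates rather than an exception.
    """
    covariates = list(covariates or [])
    df = cohort if subset is None else cohort[subset]
    if len(df) == 0:
        raise ValueError("empty cohort")
    if reference_arm is None:
        reference_arm = sorted(df[treatment_var].astype(str).unique())[0]
    X, treat_cols = _design(df, treatment_var, covariates, reference_arm, duration_col, event_col)
    n_events = int(X["_E"].sum())
    if n_events == 0:
        raise ValueError("no events in the analysis subset")
    if (X["_T"] <= 0).any():
        raise ValueError("event times must be positive")

    cph = CoxPHFitter()
    estimates = [
        HazardRatioEstimate(
            term=f"{treatment_var}={reference_arm}", hr=1.0, ci_low=1.0, ci_high=1.0,
            adjusted=bool(covariates), covariates=covariates,
            reference_arm=reference_arm, is_reference=True,
        )
    ]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(X, duration_col="_T", event_col="_E")
    except ConvergenceError as err:
        for col in treat_cols:
            estimates.append(HazardRatioEstimate(
                term=col, hr=float("nan"), ci_low=float("nan"), ci_high=float("nan"),
                adjusted=bool(covariates), covariates=covariates, reference_arm=reference_arm,
                converged=False, note=f"non-convergence: {err}",
            ))
        return CoxFitResult(estimates, n=len(X), n_events=n_events,
                            log_likelihood=float("nan"), log_likelihood_null=float("nan"))

    summ = cph.summary
    for col in treat_cols:
        row = summ.loc[col]
        estimates.append(HazardRatioEstimate(
            term=col,
            hr=float(row["exp(coef)"]),
            ci_low=float(row["exp(coef) lower 95%"]),
            ci_high=float(row["exp(coef) upper 95%"]),
            adjusted=bool(covariates),
            covariates=covariates,
            reference_arm=reference_arm,
        ))
    ll = float(cph.log_likelihood_)
    lr_stat = float(cph.log_likelihood_ratio_test().test_statistic)
    return CoxFitResult(estimates, n=len(X), n_events=n_events,
                        log_likelihood=ll, log_likelihood_null=ll - lr_stat / 2.0)


def subgroup_effects(
    cohort: pd.DataFrame,
    treatment_var: str,
    covariates: list[str],
    stratifier: str | pd.Series,
    reference_arm: str | None = None,
    **kwargs,
) -> tuple[dict[str, CoxFitResult], list[str]]:
    """Per-stratum Cox fits for moderation analysis.

    The stratifier is excluded from the covariate list; strata without
    events (or where the fit is impossible) are skipped and reported in the
    returned log.
    """
    strat = cohort[stratifier] if isinstance(stratifier, str) else stratifier
    covs = [c for c in covariates if c != stratifier]
    results: dict[str, CoxFitResult] = {}
    skipped: list[str] = []
    for level in sorted(strat.dropna().astype(str).unique()):
        mask = strat.astype(str) == level
        try:
            results[level] = fit_cox(
                cohort, treatment_var, covs, subset=mask, reference_arm=reference_arm, **kwargs
            )
        except ValueError as err:
            skipped.append(f"{level}: {err}")
    return results, skipped
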