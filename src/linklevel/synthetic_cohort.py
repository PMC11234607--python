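"""Synthetic two-source cohort generator.

Produces paired cancer-registry and insurance-claims tables for five cancer
strata (thyroid TC, gastric GC, breast BC, prostate PC, cervical CC) with a
known ground-truth pairing, so record-linkage errors and their downstream
analytic consequences can be measured exactly.

Each simulated person carries

* a unique opaque identifier (``uid``, standing in for a resident
  registration number) — the *direct* identifier,
* quasi-identifiers ``(name_key, dob, sex)`` — the *indirect* identifiers,
  deliberately non-unique because name tokens come from a finite dictionary,
* baseline covariates (age, residence, insurance type, premium quantile,
  Charlson comorbidity category, SEER summary stage),
* a stratum-specific treatment arm, and
* an osteoporotic-fracture outcome simulated from a proportional-hazards
  model with an exponential baseline hazard.

Event times are drawn by inverse-CDF sampling: ``T = -log(U) / (lam *
exp(x'beta))`` with administrative censoring at a configurable horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CANCER_TYPES = ("TC", "GC", "BC", "PC", "CC")

#: strata restricted to one sex by the disease itself
SEX_BY_CANCER = {"BC": "F", "CC": "F", "PC": "M"}

CCI_LEVELS = ("0-1", "2", "3", ">=4")
SEER_STAGES = ("localized", "regional", "distant", "unknown")
INSURANCE_TYPES = ("employee", "local", "medical-aid")
FRACTURE_SITES = ("hip", "vertebral", "distal-radius", "proximal-humerus")
#: cervical-cancer outcome is pelvic insufficiency fracture only
CC_FRACTURE_SITE = "pelvic-insufficiency"


@dataclass
class PersonRecord:
    """One simulated individual (a row view of the population table)."""

    uid: str
    name_key: str
    dob: str
    sex: str
    cancer_type: str
    seer_stage: str
    age_years: int
    residence: str
    insurance: str
    premium_quantile: int
    cci_category: str
    treatment_arm: str
    diagnosis_date: str
    index_date: str
    event_time_years: float | None = None
    event_indicator: str | None = None
    fracture_site: str | None = None

    @classmethod
    def from_row(cls, row: pd.Series) -> "PersonRecord":
        return cls(**{f: row[f] for f in cls.__dataclass_fields__})


@dataclass
class StratumConfig:
    """Per-cancer-stratum piece of the data-generating process.

    ``treatment_prevalence`` maps arm label -> probability (sums to 1);
    ``true_log_hr`` maps each non-reference arm -> true log hazard ratio
    against ``reference_arm``; ``baseline_hazard_rate`` is the exponential
    baseline event rate per person-year.
    """

    n: int
    treatment_prevalence: dict[str, float]
    reference_arm: str
    true_log_hr: dict[str, float]
    baseline_hazard_rate: float
    age_mean: float = 55.0
    age_sd: float = 12.0
    seer_stage_probs: tuple[float, ...] = (0.60, 0.25, 0.08, 0.07)

    def validate(self, name: str) -> None:
        if self.n < 0:
            raise ValueError(f"{name}: n must be >= 0, got {self.n}")
        probs = list(self.treatment_prevalence.values())
        if any(p < 0 or p > 1 for p in probs):
            raise ValueError(f"{name}: treatment prevalences must lie in [0, 1]")
        if self.treatment_prevalence and abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"{name}: treatment prevalences must sum to 1")
        if self.reference_arm not in self.treatment_prevalence:
            raise ValueError(f"{name}: reference arm {self.reference_arm!r} has no prevalence")
        if self.baseline_hazard_rate <= 0:
            raise ValueError(f"{name}: baseline hazard rate must be positive")
        for arm in self.true_log_hr:
            if arm not in self.treatment_prevalence:
                raise ValueError(f"{name}: log-HR given for unknown arm {arm!r}")


@dataclass
class ScenarioConfig:
    """Full data-generating configuration: strata plus shared parameters.

    ``covariate_effects`` holds log-hazard coefficients: a float for numeric
    covariates (per unit) or a level->coefficient map for categoricals.
    All randomness flows from ``seed`` through a single generator.
    """

    strata: dict[str, StratumConfig]
    admin_censor_years: float = 10.0
    covariate_effects: dict[str, object] = field(default_factory=dict)
    name_dictionary_size: int = 4000
    index_lag_days: int = 30
    seed: int = 0

    def __post_init__(self) -> None:
        if self.admin_censor_years <= 0:
            raise ValueError("admin_censor_years must be positive")
        if self.name_dictionary_size < 1:
            raise ValueError("name_dictionary_size must be >= 1")
        for name, stratum in self.strata.items():
            if name not in CANCER_TYPES:
                raise ValueError(f"unknown cancer stratum {name!r}")
            stratum.validate(name)

    @property
    def n_total(self) -> int:
        return sum(s.n for s in self.strata.values())

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioConfig":
        d = dict(d)
        d["strata"] = {
            k: v if isinstance(v, StratumConfig) else StratumConfig(**_tupled(v))
            for k, v in d["strata"].items()
        }
        return cls(**d)


def _tupled(d: dict) -> dict:
    d = dict(d)
    if "seer_stage_probs" in d:
        d["seer_stage_probs"] = tuple(d["seer_stage_probs"])
    return d


# Default true log-HRs follow the direct-identifier-level adjusted hazard
# ratios reported for these treatments (vitamin D 0.83; gastrectomy ~1.26
# vs endoscopic resection; AI 1.03 / tamoxifen 0.80 / AI+TAM 0.94 vs no
# hormone therapy; ADT 1.96; radiotherapy 1.80).
_DEFAULT_STRATA: dict[str, dict] = {
    "TC": dict(
        n=20_000,
        treatment_prevalence={"none": 0.55, "vitamin-D": 0.45},
        reference_arm="none",
        true_log_hr={"vitamin-D": np.log(0.83)},
        baseline_hazard_rate=0.010,
        age_mean=48.0,
        age_sd=11.0,
    ),
    "GC": dict(
        n=14_000,
        treatment_prevalence={"ESD-EMR": 0.30, "subtotal-gastrectomy": 0.50, "total-gastrectomy": 0.20},
        reference_arm="ESD-EMR",
        true_log_hr={"subtotal-gastrectomy": np.log(1.26), "total-gastrectomy": np.log(1.40)},
        baseline_hazard_rate=0.012,
        age_mean=60.0,
        age_sd=11.0,
    ),
    "BC": dict(
        n=10_000,
        treatment_prevalence={"non-HT": 0.35, "AI-only": 0.30, "TAM-only": 0.30, "AI+TAM": 0.05},
        reference_arm="non-HT",
        true_log_hr={"AI-only": np.log(1.03), "TAM-only": np.log(0.80), "AI+TAM": np.log(0.94)},
        baseline_hazard_rate=0.012,
        age_mean=52.0,
        age_sd=11.0,
    ),
    "PC": dict(
        n=7_000,
        treatment_prevalence={"non-ADT": 0.55, "ADT": 0.45},
        reference_arm="non-ADT",
        true_log_hr={"ADT": np.log(1.96)},
        baseline_hazard_rate=0.014,
        age_mean=68.0,
        age_sd=8.0,
        seer_stage_probs=(0.55, 0.30, 0.10, 0.05),
    ),
    "CC": dict(
        n=2_500,
        treatment_prevalence={"non-RT": 0.60, "RT": 0.40},
        reference_arm="non-RT",
        true_log_hr={"RT": np.log(1.80)},
        baseline_hazard_rate=0.010,
        age_mean=54.0,
        age_sd=12.0,
    ),
}

#: default log-hazard coefficients for baseline covariates
_DEFAULT_COVARIATE_EFFECTS: dict[str, object] = {
    "age_c": 0.030,  # per year above 55
    "cci_category": {"0-1": 0.0, "2": 0.15, "3": 0.30, ">=4": 0.50},
}


def single_stratum_scenario(
    n: int,
    true_hr: float,
    baseline_hazard_rate: float = 0.01,
    seed: int = 0,
    cancer_type: str = "CC",
    treatment_prevalence: dict[str, float] | None = None,
) -> ScenarioConfig:
    """One balanced two-arm stratum with the default covariate effects —
    the workhorse for parameter-recovery and bias experiments."""
    strat = StratumConfig(
        n=n,
        treatment_prevalence=treatment_prevalence or {"ctrl": 0.5, "trt": 0.5},
        reference_arm="ctrl",
        true_log_hr={"trt": float(np.log(true_hr))},
        baseline_hazard_rate=baseline_hazard_rate,
    )
    return ScenarioConfig(
        strata={cancer_type: strat},
        covariate_effects=dict(_DEFAULT_COVARIATE_EFFECTS),
        seed=seed,
    )


def default_scenario(scale: float = 1.0, seed: int = 0) -> ScenarioConfig:
    """Reference five-stratum scenario; ``scale`` shrinks every stratum."""
    strata = {}
    for name, kw in _DEFAULT_STRATA.items():
        kw = dict(kw)
        kw["n"] = max(0, int(round(kw["n"] * scale)))
        strata[name] = StratumConfig(**kw)
    return ScenarioConfig(
        strata=strata,
        covariate_effects=dict(_DEFAULT_COVARIATE_EFFECTS),
        seed=seed,
    )


# ---------------------------------------------------------------------------
# population generation

_COVARIATE_DISTS = {
    "residence": (("urban", "rural"), (0.72, 0.28)),
    "insurance": (INSURANCE_TYPES, (0.55, 0.40, 0.05)),
    "cci_category": (CCI_LEVELS, (0.55, 0.20, 0.13, 0.12)),
}


def generate_population(config: ScenarioConfig, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Draw the full population table (one row per `PersonRecord`).

    Deterministic given ``config.seed`` (or an explicit ``rng``).  Outcome
    columns are left empty; fill them with :func:`simulate_outcomes`.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    frames = []
    offset = 0
    for cancer, stratum in sorted(config.strata.items()):
        frames.append(_generate_stratum(cancer, stratum, config, rng, offset))
        offset += stratum.n
    if not frames:
        return _empty_population()
    pop = pd.concat(frames, ignore_index=True)
    return pop


def _empty_population() -> pd.DataFrame:
    cols = list(PersonRecord.__dataclass_fields__)
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def _generate_stratum(
    cancer: str,
    stratum: StratumConfig,
    config: ScenarioConfig,
    rng: np.random.Generator,
    offset: int,
) -> pd.DataFrame:
    n = stratum.n
    uid = [f"U{offset + i:07d}" for i in range(n)]
    name_key = [f"N{k:05d}" for k in rng.integers(0, config.name_dictionary_size, size=n)]
    if cancer in SEX_BY_CANCER:
        sex = np.full(n, SEX_BY_CANCER[cancer])
    else:
        sex = rng.choice(["M", "F"], size=n)

    age = np.clip(np.round(rng.normal(stratum.age_mean, stratum.age_sd, size=n)), 18, 95).astype(int)
    diagnosis = pd.Timestamp("2008-01-01") + pd.to_timedelta(
        rng.integers(0, 9 * 365, size=n), unit="D"
    )
    # DOB consistent with age at diagnosis, uniform within-year offset
    dob = diagnosis - pd.to_timedelta(age * 365.25 + rng.integers(0, 365, size=n), unit="D")
    index_date = diagnosis + pd.Timedelta(days=config.index_lag_days)

    cols: dict[str, np.ndarray | list] = {}
    for var, (levels, probs) in _COVARIATE_DISTS.items():
        cols[var] = rng.choice(levels, size=n, p=probs)
    # premium quantile: 0 reserved for medical aid, 1-10 otherwise
    premium = rng.integers(1, 11, size=n)
    premium[np.asarray(cols["insurance"]) == "medical-aid"] = 0
    seer = rng.choice(SEER_STAGES, size=n, p=stratum.seer_stage_probs)

    arms = list(stratum.treatment_prevalence)
    arm_probs = [stratum.treatment_prevalence[a] for a in arms]
    treatment = rng.choice(arms, size=n, p=arm_probs)

    return pd.DataFrame(
        {
            "uid": uid,
            "name_key": name_key,
            "dob": dob.strftime("%Y-%m-%d"),
            "sex": sex,
            "cancer_type": cancer,
            "seer_stage": seer,
            "age_years": age,
            "residence": cols["residence"],
            "insurance": cols["insurance"],
            "premium_quantile": premium,
            "cci_category": cols["cci_category"],
            "treatment_arm": treatment,
            "diagnosis_date": diagnosis.strftime("%Y-%m-%d"),
            "index_date": index_date.strftime("%Y-%m-%d"),
            "event_time_years": np.nan,
            "event_indicator": pd.Series([None] * n, dtype=object),
            "fracture_site": pd.Series([None] * n, dtype=object),
        }
    )


def linear_predictor(pop: pd.DataFrame, config: ScenarioConfig) -> np.ndarray:
    """Log-hazard linear predictor x'beta for every row.

    Treatment effects come from each stratum's ``true_log_hr``; covariate
    terms from ``config.covariate_effects``.  ``age_c`` denotes age centred
    at 55 years.
    """
    lp = np.zeros(len(pop))
    for cancer, stratum in config.strata.items():
        mask = (pop["cancer_type"] == cancer).to_numpy()
        for arm, beta in stratum.true_log_hr.items():
            lp[mask & (pop["treatment_arm"] == arm).to_numpy()] += beta
    for cov, eff in config.covariate_effects.items():
        if cov == "age_c":
            lp += float(eff) * (pop["age_years"].to_numpy(float) - 55.0)
        elif isinstance(eff, dict):
            lp += pop[cov].map(eff).fillna(0.0).to_numpy(float)
        else:
            lp += float(eff) * pop[cov].to_numpy(float)
    return lp


def simulate_outcomes(
    pop: pd.DataFrame, config: ScenarioConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Fill event times/indicators by inverse-CDF proportional-hazards sampling.

    T = -log(U) / (lam * exp(x'beta)); administrative censoring at
    ``config.admin_censor_years`` (death/emigration folded into it).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    pop = pop.copy()
    if len(pop) == 0:
        return pop
    lam = pop["cancer_type"].map(
        {c: s.baseline_hazard_rate for c, s in config.strata.items()}
    ).to_numpy(float)
    if np.any(~np.isfinite(lam)) or np.any(lam <= 0):
        raise ValueError("baseline hazard rate must be positive for every stratum present")
    u = rng.uniform(size=len(pop))
    t = -np.log(u) / (lam * np.exp(linear_predictor(pop, config)))
    censored = t > config.admin_censor_years
    pop["event_time_years"] = np.where(censored, config.admin_censor_years, t)
    pop["event_indicator"] = np.where(censored, "censored", "fracture")
    site = np.where(
        pop["cancer_type"] == "CC",
        CC_FRACTURE_SITE,
        rng.choice(FRACTURE_SITES, size=len(pop), p=(0.18, 0.32, 0.38, 0.12)),
    )
    pop["fracture_site"] = pd.Series(np.where(censored, None, site), index=pop.index, dtype=object)
    return pop


# ---------------------------------------------------------------------------
# source-table emission

REGISTRY_COLUMNS = ["record_id", "uid", "name_key", "dob", "sex", "cancer_type", "seer_stage", "diagnosis_date"]
CLAIMS_COLUMNS = [
    "record_id", "uid", "name_key", "dob", "sex", "age_years", "residence", "insurance",
    "premium_quantile", "cci_category", "treatment_arm", "index_date",
    "event_time_years", "event_indicator", "fracture_site",
]


def emit_source_tables(pop: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    """Split the population into registry and claims views plus a truth map.

    ``record_id`` is a per-table row handle never used for linkage; the truth
    map pairs registry and claims handles of the same person, which stays
    valid after identifiers are corrupted.
    """
    n = len(pop)
    registry = pop.reindex(columns=[c for c in REGISTRY_COLUMNS if c != "record_id"]).copy()
    registry.insert(0, "record_id", [f"R{i:07d}" for i in range(n)])
    claims = pop.reindex(columns=[c for c in CLAIMS_COLUMNS if c != "record_id"]).copy()
    claims.insert(0, "record_id", [f"C{i:07d}" for i in range(n)])
    truth = [
        {"registry_id": r, "claims_id": c, "uid": u}
        for r, c, u in zip(registry["record_id"], claims["record_id"], pop.get("uid", []))
    ]
    return registry, claims, truth


def write_source_tables(
    outdir: str | Path,
    registry: pd.DataFrame,
    claims: pd.DataFrame,
    truth: list[dict],
    config: ScenarioConfig | None = None,
) -> dict[str, Path]:
    """Serialize tables as CSV with a JSON truth sidecar (and a config echo)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "registry": outdir / "registry.csv",
        "claims": outdir / "claims.csv",
        "truth": outdir / "truth.json",
    }
    registry.to_csv(paths["registry"], index=False)
    claims.to_csv(paths["claims"], index=False)
    paths["truth"].write_text(json.dumps(truth, indent=1))
    if config is not None:
        paths["scenario"] = outdir / "scenario.yaml"
        paths["scenario"].write_text(yaml.safe_dump(_yaml_safe(config.to_dict()), sort_keys=True))
    return paths


def _yaml_safe(obj):
    if isinstance(obj, dict):
        return {k: _yaml_safe(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_yaml_safe(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def read_source_tables(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, list[dict]]:
    outdir = Path(outdir)
    registry = pd.read_csv(outdir / "registry.csv", dtype={"record_id": str, "uid": str})
    claims = pd.read_csv(outdir / "claims.csv", dtype={"record_id": str, "uid": str})
    truth = json.loads((outdir / "truth.json").read_text())
    return registry, claims, truth
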