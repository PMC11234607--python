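"""Concordance scoring between analysis results at two linkage levels.

Treating the direct-identifier (DII) linked cohort's results as the gold
standard, each paired result from the indirect-identifier (III) cohort is
scored with an effect size for the discrepancy:

* Cohen's h = |2·arcsin√p₁ − 2·arcsin√p₂| for proportions,
* Cohen's f = √(R²/(1−R²)) for model explanatory power,
* for hazard ratios, each HR is mapped to p = HR/(1+HR) and Cohen's h is
  applied to the pair — a package convention chosen because it reproduces
  the typical printed magnitudes for near-equal HRs (0 for identical HRs,
  ≈0.01 for 1.24 vs 1.26).

Effect sizes are binned (none / very small / small / medium / large) and a
decision table turns each paired comparison into a three-tier study-level
verdict: good (○), poor (△) or insufficient (X).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

INTERPRETATION_BINS = (
    (0.01, "none"),
    (0.2, "very small"),
    (0.5, "small"),
    (0.8, "medium"),
    (float("inf"), "large"),
)


class Verdict(str, Enum):
    GOOD = "good"
    POOR = "poor"
    INSUFFICIENT = "insufficient"

    @property
    def symbol(self) -> str:
        return {"good": "○", "poor": "△", "insufficient": "X"}[self.value]

    @property
    def rank(self) -> int:
        return {"good": 0, "poor": 1, "insufficient": 2}[self.value]


SYMBOL_TO_VERDICT = {"○": Verdict.GOOD, "△": Verdict.POOR, "X": Verdict.INSUFFICIENT}


@dataclass
class EffectSizeResult:
    family: str  # cohens_h | cohens_f | hr_h
    value: float
    inputs: tuple
    interpretation: str


@dataclass
class IntervalEstimate:
    """Point estimate with a two-sided confidence interval."""

    point: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if self.ci_low > self.ci_high:
            raise ValueError(f"malformed CI: [{self.ci_low}, {self.ci_high}]")

    def excludes(self, reference: float) -> bool:
        return reference < self.ci_low or reference > self.ci_high

    def side(self, reference: float) -> int:
        return int(np.sign(self.point - reference))


@dataclass
class ConcordanceVerdict:
    level: Verdict
    effect_size: EffectSizeResult
    direction_agrees: bool
    significant_opposite: bool
    rationale: str

    @property
    def symbol(self) -> str:
        return self.level.symbol


def interpret_effect_size(value: float) -> str:
    """Bin a non-negative effect size (half-open bins, lower bound inclusive)."""
    if value < 0:
        raise ValueError("effect size must be non-negative")
    for upper, label in INTERPRETATION_BINS:
        if value < upper:
            return label
    raise AssertionError("unreachable")


def cohens_h(p1: float, p2: float) -> EffectSizeResult:
    """Arcsine effect size for two proportions: |2 arcsin√p1 − 2 arcsin√p2|."""
    for p in (p1, p2):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"proportion {p} outside [0, 1]")
    value = float(abs(2.0 * np.arcsin(np.sqrt(p1)) - 2.0 * np.arcsin(np.sqrt(p2))))
    return EffectSizeResult("cohens_h", value, (p1, p2), interpret_effect_size(value))


def cohens_f(r_squared: float) -> EffectSizeResult:
    """Effect size for model explanatory power: f = √(R² / (1 − R²))."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError(f"R² must lie in [0, 1), got {r_squared}")
    value = float(np.sqrt(r_squared / (1.0 - r_squared)))
    return EffectSizeResult("cohens_f", value, (r_squared,), interpret_effect_size(value))


def hr_effect_size(hr_a: float, hr_b: float) -> EffectSizeResult:
    """Discrepancy between two hazard ratios via the HR/(1+HR) arcsine map.

    Symmetric in its arguments and zero iff the HRs are equal.
    """
    if hr_a <= 0 or hr_b <= 0:
        raise ValueError("hazard ratios must be positive")
    h = cohens_h(hr_a / (1.0 + hr_a), hr_b / (1.0 + hr_b))
    return EffectSizeResult("hr_h", h.value, (hr_a, hr_b), h.interpretation)


def classify_study_level(
    effect: EffectSizeResult,
    estimate_a: IntervalEstimate | None = None,
    estimate_b: IntervalEstimate | None = None,
    direction_reference: float | None = None,
) -> ConcordanceVerdict:
    """Three-tier verdict for one paired comparison (decision table, top-down).

    1. opposite directions and both CIs exclude the reference → insufficient;
    2. effect ≥ 0.8 → insufficient;
    3. 0.5 ≤ effect < 0.8 → poor;
    4. opposite directions, not significantly so → poor;
    5. otherwise → good.

    ``direction_reference`` is the neutral value (1 for ratios, 0 for
    differences); when None — e.g. for descriptive proportions, which have
    no effect direction — rules 1 and 4 cannot fire.
    """
    direction_agrees = True
    significant_opposite = False
    if direction_reference is not None and estimate_a is not None and estimate_b is not None:
        sa, sb = estimate_a.side(direction_reference), estimate_b.side(direction_reference)
        direction_agrees = sa == sb or sa == 0 or sb == 0
        significant_opposite = (
            not direction_agrees
            and estimate_a.excludes(direction_reference)
            and estimate_b.excludes(direction_reference)
        )
    if significant_opposite:
        level, why = Verdict.INSUFFICIENT, "significantly estimated in opposite directions (rule 1)"
    elif effect.value >= 0.8:
        level, why = Verdict.INSUFFICIENT, f"effect size {effect.value:.2f} >= 0.8 (rule 2)"
    elif effect.value >= 0.5:
        level, why = Verdict.POOR, f"effect size {effect.value:.2f} in [0.5, 0.8) (rule 3)"
    elif not direction_agrees:
        level, why = Verdict.POOR, "opposite directions but not significant (rule 4)"
    else:
        level, why = Verdict.GOOD, f"effect size {effect.value:.2f} < 0.5, directions agree (rule 5)"
    return ConcordanceVerdict(level, effect, direction_agrees, significant_opposite, why)


# ---------------------------------------------------------------------------
# paired-result reporting

@dataclass
class ComparableResult:
    """One analysis output prepared for cross-level comparison.

    ``kind`` selects the effect-size family: "proportion" (Cohen's h on the
    point values, no direction) or "hr" (the HR arcsine map, direction
    reference 1).  Model explanatory power is reported separately through
    `cohens_f` rather than paired here.
    """

    key: tuple  # (stratum, analysis_method, item)
    kind: str  # proportion | hr
    point: float
    ci_low: float | None = None
    ci_high: float | None = None
    n: int | None = None

    def interval(self) -> IntervalEstimate | None:
        if self.ci_low is None or self.ci_high is None:
            return None
        return IntervalEstimate(self.point, self.ci_low, self.ci_high)


@dataclass
class PairVerdict:
    key: tuple
    kind: str
    value_iii: float
    value_dii: float
    verdict: ConcordanceVerdict | None
    missing_in: str | None = None


def compare_pair(res_iii: ComparableResult, res_dii: ComparableResult) -> ConcordanceVerdict:
    if res_iii.kind != res_dii.kind:
        raise ValueError(f"kind mismatch at {res_iii.key}: {res_iii.kind} vs {res_dii.kind}")
    if res_iii.kind == "proportion":
        effect = cohens_h(res_iii.point, res_dii.point)
        return classify_study_level(effect, res_iii.interval(), res_dii.interval(), None)
    if res_iii.kind == "hr":
        effect = hr_effect_size(res_iii.point, res_dii.point)
        return classify_study_level(effect, res_iii.interval(), res_dii.interval(), 1.0)
    raise ValueError(f"unknown comparison kind {res_iii.kind!r}")


def concordance_report(
    results_iii: list[ComparableResult],
    results_dii: list[ComparableResult],
) -> tuple[list[PairVerdict], pd.DataFrame]:
    """Pair results by key, score each, and build the verdict grid.

    Grid rows are analysis methods, columns strata; a cell shows the worst
    verdict symbol among its comparisons, "-" when no comparison applies,
    and "missing" when a key appears at only one level.
    """
    by_key_iii = {r.key: r for r in results_iii}
    by_key_dii = {r.key: r for r in results_dii}
    pairs: list[PairVerdict] = []
    for key in sorted(set(by_key_iii) | set(by_key_dii), key=str):
        a, b = by_key_iii.get(key), by_key_dii.get(key)
        if a is None or b is None:
            missing_in = "III" if a is None else "DII"
            present = b if a is None else a
            pairs.append(PairVerdict(key, present.kind, np.nan, np.nan, None, missing_in))
            continue
        verdict = compare_pair(a, b)
        pairs.append(PairVerdict(key, a.kind, a.point, b.point, verdict))

    methods = sorted({p.key[1] for p in pairs})
    strata = sorted({p.key[0] for p in pairs})
    grid = pd.DataFrame("-", index=methods, columns=strata)
    for p in pairs:
        stratum, method = p.key[0], p.key[1]
        cell = grid.loc[method, stratum]
        if p.verdict is None:
            if cell == "-":
                grid.loc[method, stratum] = "missing"
            continue
        sym = p.verdict.symbol
        if cell in ("-", "missing"):
            grid.loc[method, stratum] = sym
        else:
            worst = max(SYMBOL_TO_VERDICT[cell], SYMBOL_TO_VERDICT[sym], key=lambda v: v.rank)
            grid.loc[method, stratum] = worst.symbol
    return pairs, grid


def render_grid(grid: pd.DataFrame) -> str:
    """Plain-text verdict grid (○ = good, △ = poor, X = insufficient)."""
    out = grid.copy()
    out.index.name = "analysis method"
    legend = "legend: ○ = good, △ = poor, X = insufficient, - = not applicable"
    return out.to_string() + "\n" + legend
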