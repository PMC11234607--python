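"""Deterministic composite-key linkage with controlled error injection.

Two linkage levels are supported:

* ``DII`` (directly identifiable information): the key is the unique person
  identifier ``uid`` — exact one-to-one linkage whenever the uid survives.
* ``III`` (indirectly identifiable information): the key is the composite of
  the quasi-identifiers ``(name_key, dob, sex)`` — usually but not always
  unique, so identifier discrepancies produce *missed matches* and key
  collisions produce *false matches*.

`corrupt_identifiers` injects both error types at configurable rates into
one source table; `link` performs exact-match joining with a deterministic
tie rule; `account` produces the flow-chart-style error accounting (counts,
percentages and the linkage rate of one level relative to another).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

LEVELS = ("DII", "III")
III_FIELDS = ("name_key", "dob", "sex")

TRUE_MATCH = "true-match"
FALSE_MATCH = "false-match"


@dataclass
class ErrorModel:
    """Identifier-error process for one source table.

    miss_rate
        Probability a record's quasi-identifiers are perturbed so its III
        key no longer equals its partner's (a missed match at III level).
    collision_rate
        Probability a record's quasi-identifiers are overwritten with
        another individual's (an engineered III key collision, i.e. a false
        match).
    dii_miss_rate
        Probability the unique identifier is blanked (missed match at DII
        level).
    informative_coeffs
        Map of pandas ``query`` predicates -> log-odds shifts applied to
        ``miss_rate`` for matching records, making missingness depend on
        covariates or outcomes.
    """

    miss_rate: float = 0.0
    collision_rate: float = 0.0
    dii_miss_rate: float = 0.0
    informative_coeffs: dict[str, float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("miss_rate", "collision_rate", "dii_miss_rate"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")

    def to_dict(self) -> dict:
        return asdict(self)

    def miss_probabilities(self, table: pd.DataFrame) -> np.ndarray:
        """Per-record miss probability after logistic covariate shifts."""
        n = len(table)
        if not self.informative_coeffs or n == 0:
            return np.full(n, self.miss_rate)
        base = np.clip(self.miss_rate, 1e-12, 1 - 1e-12)
        logit = np.full(n, np.log(base / (1 - base)))
        for predicate, shift in self.informative_coeffs.items():
            mask = table.eval(predicate).to_numpy(bool)
            logit[mask] += shift
        p = 1.0 / (1.0 + np.exp(-logit))
        if self.miss_rate == 0.0:
            p[:] = 0.0
        return np.clip(p, 0.0, 1.0)


@dataclass
class LinkageAccounting:
    """Error bookkeeping for one linked cohort (flow-chart arithmetic)."""

    level: str
    n_total: int
    n_linked: int
    n_false: int
    n_missed: int
    linkage_rate_vs_reference: float | None = None

    def __post_init__(self) -> None:
        if min(self.n_total, self.n_linked, self.n_false, self.n_missed) < 0:
            raise ValueError("counts must be non-negative")
        if self.n_missed > self.n_total:
            raise ValueError("missed matches cannot exceed truth pairs")
        if self.n_linked != (self.n_total - self.n_missed) + self.n_false:
            raise ValueError("accounting violates n_linked = n_total - n_missed + n_false")

    @property
    def false_pct(self) -> float:
        return round(100.0 * self.n_false / self.n_total, 1) if self.n_total else 0.0

    @property
    def missed_pct(self) -> float:
        return round(100.0 * self.n_missed / self.n_total, 1) if self.n_total else 0.0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["false_pct"] = self.false_pct
        d["missed_pct"] = self.missed_pct
        return d


def linkage_rate(n_linked: int, n_reference: int) -> float:
    """Linked cohort size as a percentage of a reference cohort, 1 decimal."""
    if n_reference <= 0:
        raise ValueError("reference cohort size must be positive")
    return round(100.0 * n_linked / n_reference, 1)


@dataclass
class LinkedCohort:
    """Result of joining registry and claims at one linkage level.

    ``rows`` carries both payloads (suffixes ``_registry`` / ``_claims``)
    plus a ``provenance`` column (true-match or false-match); ``collisions``
    lists same-source duplicate-key records dropped by the tie rule;
    ``unlinkable`` counts records with missing key fields per source.
    """

    level: str
    rows: pd.DataFrame
    collisions: pd.DataFrame
    unlinkable: dict[str, int]

    @property
    def n_linked(self) -> int:
        return len(self.rows)

    @property
    def n_false(self) -> int:
        return int((self.rows["provenance"] == FALSE_MATCH).sum()) if self.n_linked else 0


# ---------------------------------------------------------------------------
# keys

def make_composite_key(record: pd.Series | dict, level: str) -> str | None:
    """Deterministic composite key for one record, or None if unlinkable.

    DII keys depend only on ``uid``; III keys only on (name_key, dob, sex).
    """
    _check_level(level)
    if level == "DII":
        uid = record.get("uid")
        return None if _missing(uid) else f"uid:{uid}"
    parts = [record.get(f) for f in III_FIELDS]
    if any(_missing(p) for p in parts):
        return None
    return "|".join(str(p) for p in parts)


def composite_keys(table: pd.DataFrame, level: str) -> pd.Series:
    """Vectorized `make_composite_key` over a table."""
    _check_level(level)
    if len(table) == 0:
        return pd.Series(dtype=object)
    if level == "DII":
        uid = table["uid"]
        keys = "uid:" + uid.astype(str)
        return keys.where(~uid.isna() & (uid.astype(str) != ""), None)
    ok = pd.Series(True, index=table.index)
    for f in III_FIELDS:
        ok &= ~table[f].isna() & (table[f].astype(str) != "")
    keys = (
        table["name_key"].astype(str) + "|" + table["dob"].astype(str) + "|" + table["sex"].astype(str)
    )
    return keys.where(ok, None)


def _missing(v) -> bool:
    return v is None or (isinstance(v, float) and np.isnan(v)) or v == ""


def _check_level(level: str) -> None:
    if level not in LEVELS:
        raise ValueError(f"level must be one of {LEVELS}, got {level!r}")


# ---------------------------------------------------------------------------
# corruption

MISS = "miss"
COLLISION = "collision"
COLLISION_DISPLACED = "collision-displaced"
DII_MISS = "dii-miss"


def corrupt_identifiers(
    table: pd.DataFrame, error_model: ErrorModel
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the identifier-error process to one source table.

    Returns the corrupted copy and a log with one row per change
    (``record_id``, ``kind``, ``field``, ``old``, ``new``).  Deterministic
    given ``error_model.seed``.  Collisions are *engineered*: the victim's
    quasi-identifiers are replaced by a donor's, and the donor's own record
    is displaced (its dob perturbed) so the false-match count tracks
    ``collision_rate`` rather than tie-rule luck.
    """
    table = table.copy()
    n = len(table)
    log_entries: list[dict] = []
    if n == 0:
        return table, _empty_log()
    rng = np.random.default_rng(error_model.seed)

    # draw all three processes up-front; a collision pre-empts a miss on the
    # same record so realized false-match counts track collision_rate
    p_miss = error_model.miss_probabilities(table)
    miss_draw = rng.uniform(size=n) < p_miss
    coll_draw = rng.uniform(size=n) < error_model.collision_rate
    dii_draw = rng.uniform(size=n) < error_model.dii_miss_rate

    coll_idx = np.flatnonzero(coll_draw)
    miss_idx = np.flatnonzero(miss_draw & ~coll_draw)
    # donate from records already slated for a miss perturbation (their own
    # III key is broken regardless), falling back to clean donors that then
    # need explicit displacement
    miss_pool = miss_idx.copy()
    clean_pool = np.flatnonzero(~coll_draw & ~miss_draw)
    rng.shuffle(miss_pool)
    rng.shuffle(clean_pool)
    donor_pool = np.concatenate([miss_pool, clean_pool])
    donors = donor_pool[: len(coll_idx)]
    coll_idx = coll_idx[: len(donors)]
    needs_displacement = set(clean_pool[: max(0, len(coll_idx) - len(miss_pool))].tolist())

    record_id = table["record_id"].to_numpy(object)
    ident = {f: table[f].to_numpy(object).copy() for f in (*III_FIELDS, "uid")}
    orig = {f: table[f].to_numpy(object) for f in III_FIELDS}

    def log(i: int, kind: str, fld: str, old, new) -> None:
        log_entries.append({"record_id": record_id[i], "kind": kind, "field": fld, "old": old, "new": new})

    def perturb(i: int, kind: str) -> None:
        # name-token swap or dob digit-style edit, either breaks the III key
        if rng.uniform() < 0.5:
            old = ident["name_key"][i]
            new = f"X{rng.integers(0, 10**6):06d}"
            ident["name_key"][i] = new
            log(i, kind, "name_key", old, new)
        else:
            old = ident["dob"][i]
            new = (pd.Timestamp(old) + pd.Timedelta(days=int(rng.integers(1, 365)))).strftime("%Y-%m-%d")
            ident["dob"][i] = new
            log(i, kind, "dob", old, new)

    displaced = set()
    for i, j in zip(coll_idx, donors):
        for fld in III_FIELDS:
            old = ident[fld][i]
            ident[fld][i] = orig[fld][j]
            log(i, COLLISION, fld, old, ident[fld][i])
        if j in needs_displacement and j not in displaced:
            perturb(j, COLLISION_DISPLACED)
            displaced.add(j)

    for i in miss_idx:
        perturb(i, MISS)

    for i in np.flatnonzero(dii_draw):
        log(i, DII_MISS, "uid", ident["uid"][i], None)
        ident["uid"][i] = None

    for f, col in ident.items():
        table[f] = col
    return table, (pd.DataFrame(log_entries) if log_entries else _empty_log())


def _empty_log() -> pd.DataFrame:
    return pd.DataFrame(columns=["record_id", "kind", "field", "old", "new"])


# ---------------------------------------------------------------------------
# linkage

def link(
    registry: pd.DataFrame,
    claims: pd.DataFrame,
    level: str,
    truth: list[dict] | None = None,
) -> LinkedCohort:
    """Exact-match inner join on the level's composite key.

    Duplicate keys within one source are resolved deterministically: the
    earliest-index record keeps the key, the rest go to the collision
    report.  Provenance is assigned by comparing linked record-id pairs to
    the truth map (all rows labelled true-match when no truth is given).
    """
    _check_level(level)
    reg = registry.copy()
    clm = claims.copy()
    reg["_key"] = composite_keys(reg, level)
    clm["_key"] = composite_keys(clm, level)

    unlinkable = {
        "registry": int(reg["_key"].isna().sum()),
        "claims": int(clm["_key"].isna().sum()),
    }
    reg = reg[reg["_key"].notna()]
    clm = clm[clm["_key"].notna()]

    dup_r = reg.duplicated("_key", keep="first")
    dup_c = clm.duplicated("_key", keep="first")
    collisions = pd.concat(
        [reg[dup_r].assign(_source="registry"), clm[dup_c].assign(_source="claims")],
        ignore_index=True,
    )
    reg = reg[~dup_r]
    clm = clm[~dup_c]

    rows = reg.merge(clm, on="_key", how="inner", suffixes=("_registry", "_claims"))
    rows = rows.drop(columns="_key")

    if truth is not None:
        pairs = {(t["registry_id"], t["claims_id"]) for t in truth}
        if len(rows):
            linked_pairs = list(zip(rows["record_id_registry"], rows["record_id_claims"]))
            rows["provenance"] = [TRUE_MATCH if p in pairs else FALSE_MATCH for p in linked_pairs]
        else:
            rows["provenance"] = pd.Series(dtype=object)
    else:
        rows["provenance"] = TRUE_MATCH
    return LinkedCohort(level=level, rows=rows, collisions=collisions, unlinkable=unlinkable)


def account(
    linked: LinkedCohort,
    truth: list[dict],
    reference: LinkedCohort | None = None,
) -> LinkageAccounting:
    """Flow-chart accounting of one linked cohort against the truth map.

    n_missed counts truth pairs not recovered as true matches, so the
    identity ``n_linked = (n_total - n_missed) + n_false`` holds exactly.
    """
    n_total = len(truth)
    known = {t["registry_id"] for t in truth} | {t["claims_id"] for t in truth}
    if linked.n_linked:
        seen = set(linked.rows["record_id_registry"]) | set(linked.rows["record_id_claims"])
        stray = seen - known
        if stray:
            raise ValueError(f"linked records absent from truth map: {sorted(stray)[:5]}")
    n_false = linked.n_false
    n_true = linked.n_linked - n_false
    n_missed = n_total - n_true
    rate = linkage_rate(linked.n_linked, reference.n_linked) if reference is not None else None
    return LinkageAccounting(
        level=linked.level,
        n_total=n_total,
        n_linked=linked.n_linked,
        n_false=n_false,
        n_missed=n_missed,
        linkage_rate_vs_reference=rate,
    )


def render_flow(accounts: dict[str, LinkageAccounting]) -> str:
    """Human-readable linkage flow block (one section per level)."""
    lines = ["Linkage flow", "============"]
    for level, acc in accounts.items():
        lines += [
            f"[{level}] truth pairs: {acc.n_total:,}",
            f"  linked:        {acc.n_linked:,}",
            f"  false matches: {acc.n_false:,} ({acc.false_pct}%)",
            f"  missed:        {acc.n_missed:,} ({acc.missed_pct}%)",
        ]
        if acc.linkage_rate_vs_reference is not None:
            lines.append(f"  linkage rate vs reference: {acc.linkage_rate_vs_reference}%")
    return "\n".join(lines)
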