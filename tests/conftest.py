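import numpy as np
import pandas as pd
import pytest

import linklevel as ll


@pytest.fixture(scope="session")
def small_scenario() -> ll.ScenarioConfig:
    return ll.default_scenario(scale=0.02, seed=11)


@pytest.fixture(scope="session")
def small_population(small_scenario) -> pd.DataFrame:
    pop = ll.generate_population(small_scenario)
    return ll.simulate_outcomes(pop, small_scenario)


@pytest.fixture(scope="session")
def small_sources(small_population):
    return ll.emit_source_tables(small_population)


def identifier_table(n: int, seed: int = 0, dictionary: int = 10**6) -> pd.DataFrame:
    """Minimal claims-like table carrying only linkage identifiers."""
    rng = np.random.default_rng(seed)
    dob = pd.Timestamp("1950-01-01") + pd.to_timedelta(rng.integers(0, 20_000, n), unit="D")
    return pd.DataFrame(
        {
            "record_id": [f"C{i:07d}" for i in range(n)],
            "uid": [f"U{i:07d}" for i in range(n)],
            "name_key": [f"N{k:06d}" for k in rng.integers(0, dictionary, n)],
            "dob": dob.strftime("%Y-%m-%d"),
            "sex": rng.choice(["M", "F"], n),
        }
    )


@pytest.fixture
def toy_pair_tables():
    """Ten truth pairs with two corrupted claims records, one of which is an
    engineered key collision: linking at III gives 9 linked rows (1 false
    match) and 2 missed matches — enumerated by hand.

    Person 0's claims record takes over person 1's quasi-identifiers (the
    collision); person 1's claims record gets a junk name (a plain miss).
    """
    registry = identifier_table(10, seed=42)
    registry["record_id"] = [f"R{i:07d}" for i in range(10)]
    registry["cancer_type"] = "TC"
    claims = identifier_table(10, seed=42)
    truth = [
        {"registry_id": f"R{i:07d}", "claims_id": f"C{i:07d}", "uid": f"U{i:07d}"} for i in range(10)
    ]
    claims.loc[0, ["name_key", "dob", "sex"]] = registry.loc[1, ["name_key", "dob", "sex"]].to_numpy()
    claims.loc[1, "name_key"] = "JUNK"
    return registry, claims, truth
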