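import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

import sigconn as sc

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


def ks_bruteforce(tag_ranks, n):
    """Independent KS oracle: evaluate the signed sup-difference between the
    tag empirical step function and the uniform line at every rank."""
    t = len(tag_ranks)
    ecdf = lambda x: sum(v <= x for v in tag_ranks) / t
    a = max(ecdf(u) - u / n for u in range(1, n + 1))
    b = max(u / n - ecdf(u - 1) for u in range(1, n + 1))
    return a if a >= b else -b


@pytest.fixture
def tiny_db():
    """Hand-built 6-probe, 4-instance database, two compounds."""
    probes = ["pA", "pB", "pC", "pD", "pE", "pF"]
    rng = np.random.default_rng(7)
    profiles = []
    for i, (cpd, cell) in enumerate(
        [("drugX", "PC3"), ("drugX", "PC3"), ("drugY", "MCF7"), ("drugY", "PC3")]
    ):
        amps = rng.normal(size=6)
        profiles.append(
            sc.rank_profile_from_amplitudes(
                pd.Series(amps, index=probes), f"inst{i}", cpd, cell
            )
        )
    return sc.build_database(profiles)


@pytest.fixture
def small_sim():
    """Small planted simulation shared across tests."""
    cfg = sc.SimulationConfig(
        n_probes=300,
        n_compounds=8,
        instances_per_compound=3,
        tag_set_size=40,
        effect_size=3.0,
        noise_sd=1.0,
        planted=((0, "oppositional"), (1, "concordant")),
        seed=11,
    )
    db, truth = sc.simulate_database(cfg)
    return cfg, db, truth
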