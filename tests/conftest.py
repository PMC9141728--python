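import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from retrophylo.marker_matrix import (
    ABSENT,
    ORDERS,
    OUTGROUP,
    PRESENT,
    UNKNOWN,
    OrderMap,
    PresenceAbsenceMatrix,
)


@pytest.fixture
def order_map_species() -> OrderMap:
    """Two species per order plus one outgroup species (11 taxa)."""
    assignments = {}
    for order in ORDERS:
        assignments[f"{order}_sp1"] = order
        assignments[f"{order}_sp2"] = order
    assignments[f"{OUTGROUP}_sp1"] = OUTGROUP
    return OrderMap(assignments)


@pytest.fixture
def order_level_taxa() -> list[str]:
    return list(ORDERS) + [OUTGROUP]


def make_order_matrix(patterns, taxa=None):
    """Build an order-level matrix from presence-set patterns
    (iterables of order names); everything else absent."""
    taxa = taxa or (list(ORDERS) + [OUTGROUP])
    states = np.full((len(patterns), len(taxa)), ABSENT, dtype=np.int8)
    for i, pat in enumerate(patterns):
        for t in pat:
            states[i, taxa.index(t)] = PRESENT
    return PresenceAbsenceMatrix(
        [f"m{i}" for i in range(len(patterns))], list(taxa), states
    )


@pytest.fixture
def make_matrix():
    return make_order_matrix


@pytest.fixture(scope="session")
def preset_sims():
    """Fifty seeded branch-weighted simulations at the reference scenario
    (shared by the symmetry and topology-recovery checks)."""
    from retrophylo.simulator import laurasiatheria_preset, simulate_markers

    out = []
    for seed in range(50):
        scenario = laurasiatheria_preset(seed=seed)
        out.append(simulate_markers(scenario))
    return out
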