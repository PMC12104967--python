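import numpy as np
import pytest

from pocketfish.io import AffinityTable, LigandRecord, LigandRole
from pocketfish.simulate import (
    SimulationParams,
    default_planted_pairs,
    simulate_affinity,
)


@pytest.fixture
def small_manifest() -> list[LigandRecord]:
    """2 query + 4 inactive ligands."""
    return [
        LigandRecord("Q01", LigandRole.QUERY),
        LigandRecord("Q02", LigandRole.QUERY),
        LigandRecord("I01", LigandRole.INACTIVE),
        LigandRecord("I02", LigandRole.INACTIVE),
        LigandRecord("I03", LigandRole.INACTIVE),
        LigandRecord("I04", LigandRole.INACTIVE),
    ]


@pytest.fixture
def small_table(small_manifest) -> AffinityTable:
    """Complete 6-ligand x 20-pocket matrix, deterministic."""
    rng = np.random.default_rng(42)
    ligands = [r.ligand_id for r in small_manifest]
    pockets = [f"p{j:03d}" for j in range(20)]
    score = {
        (m, p): float(rng.normal(50.0, 3.0))
        for m in ligands
        for p in pockets
    }
    return AffinityTable(ligands, pockets, score)


@pytest.fixture
def planted_instance():
    """One simulated screen with strongly planted pairs (delta = 6)."""
    planted = default_planted_pairs(2, 150, 8, seed=7)
    params = SimulationParams(
        n_pockets=150, n_query=2, n_inactive=10,
        planted=planted, delta=6.0, seed=7,
    )
    return simulate_affinity(params)
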