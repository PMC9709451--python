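import numpy as np
import pytest

from metaqtl.consensus import ConsensusMap, GeneticMap, MapEntry
from metaqtl.projection import ProjectedQTL


@pytest.fixture
def scaffold_map() -> GeneticMap:
    """Two-chromosome scaffold with markers every 10 cM."""
    entries = [
        MapEntry(f"A{c}_{i}", c, float(i * 10))
        for c in (1, 2)
        for i in range(11)
    ]
    return GeneticMap(map_id="scaffold", entries=entries)


@pytest.fixture
def scaffold_consensus(scaffold_map) -> ConsensusMap:
    """The scaffold promoted to a consensus map (identity integration)."""
    return ConsensusMap(
        map_id="consensus",
        entries=list(scaffold_map.entries),
        provenance={e.marker: "scaffold" for e in scaffold_map.entries},
    )


def make_projected(positions, sigmas, chromosome=1, trait="SF", pve=0.1):
    """Build ProjectedQTL records from raw positions/sigmas."""
    return [
        ProjectedQTL(
            qtl_id=f"q{i}",
            chromosome=chromosome,
            peak_cons_cm=float(x),
            ci95_cons_cm=float(s) * 3.92,
            sigma_cm=float(s),
            trait=trait,
            pve=pve,
        )
        for i, (x, s) in enumerate(zip(positions, sigmas))
    ]


@pytest.fixture
def projected_factory():
    return make_projected
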