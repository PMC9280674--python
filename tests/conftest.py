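import numpy as np
import pytest

from sslmap.genome_model import Marker, MarkerMap
from sslmap.synthetic_data import MB, LineRecipe, QTLSpec, SimulationConfig


@pytest.fixture
def chr5_map() -> MarkerMap:
    """Five evenly spaced markers on one chromosome (8..16 Mb)."""
    return MarkerMap(
        Marker(chromosome="chr5", position=(8 + 2 * i) * MB, name=f"m{i + 1}")
        for i in range(5)
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20170219)


def single_qtl_config(
    seed: int,
    a_fcs: float = -18.6,
    a_scs: float = -12.3,
    qtl_pos_mb: float = 16.9,
) -> SimulationConfig:
    """One-QTL study: recipient, carrier SSSL, eight NILs tiling its segment."""
    library = [
        LineRecipe("SSSL-A", (("chr5", 5 * MB, int(22.81 * MB)),)),
        LineRecipe("NIL-A1", (("chr5", int(14.5 * MB), int(22.81 * MB)),)),
        LineRecipe("NIL-A2", (("chr5", 12 * MB, int(18.5 * MB)),)),
        LineRecipe("NIL-A3", (("chr5", 16 * MB, 20 * MB),)),
        LineRecipe("NIL-A4", (("chr5", int(15.5 * MB), int(17.5 * MB)),)),
        LineRecipe("NIL-A5", (("chr5", int(16.3 * MB), int(22.81 * MB)),)),
        LineRecipe("NIL-A6", (("chr5", 5 * MB, int(12.5 * MB)),)),
        LineRecipe("NIL-A7", (("chr5", 5 * MB, int(15.5 * MB)),)),
        LineRecipe("NIL-A8", (("chr5", 18 * MB, int(22.81 * MB)),)),
    ]
    return SimulationConfig(
        seed=seed,
        chromosomes={"chr5": 30 * MB},
        qtls=[QTLSpec("qA", "chr5", int(qtl_pos_mb * MB), a_fcs=a_fcs, a_scs=a_scs, d=4.0)],
        library=library,
    )
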