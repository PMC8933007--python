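import numpy as np
import pandas as pd
import pytest

from senescape.intervals import ChromatinStateMap, IntervalSet
from senescape.matrixio import SampleMeta
from senescape.synthio import SimulationSpec


@pytest.fixture(scope="session")
def sim_spec() -> SimulationSpec:
    return SimulationSpec(seed=11)


@pytest.fixture(scope="session")
def genome(sim_spec):
    from senescape.synthio import make_genome_fixture

    return make_genome_fixture(sim_spec)


@pytest.fixture
def toy_states() -> ChromatinStateMap:
    # chr1 tiled 0..3000 by three states; chr2 by one
    iv = IntervalSet.from_records(
        [
            ("chr1", 0, 1000, "25"),
            ("chr1", 1000, 2000, "1"),
            ("chr1", 2000, 2200, "7"),
            ("chr1", 2200, 3000, "25"),
            ("chr2", 0, 3000, "13"),
        ]
    )
    return ChromatinStateMap(iv)


@pytest.fixture
def metab_meta() -> SampleMeta:
    rows = []
    for tp in (33.0, 37.0):
        for rep in (1, 2):
            rows.append((f"WT_T{int(tp)}_r{rep}", "WT", tp, rep, 1.0))
            rows.append((f"CTRL_T{int(tp)}_r{rep}", "control", tp, rep, 1.0))
    df = pd.DataFrame(
        rows, columns=["sample_id", "line", "timepoint", "replicate", "protein_conc"]
    ).set_index("sample_id")
    return SampleMeta(df)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
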