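import numpy as np
import pandas as pd
import pytest

from trufflenet import AbundanceTable, SampleMeta, SimConfig, simulate_counts


@pytest.fixture
def small_counts() -> AbundanceTable:
    return AbundanceTable(
        pd.DataFrame(
            [[10, 0], [5, 5]],
            index=["s1", "s2"],
            columns=["taxA", "taxB"],
        ),
        "counts",
    )


@pytest.fixture
def study_scale_sim():
    """Synthetic table at a realistic survey scale: 2 species x 2
    compartments x 4 replicates, 25 taxa, planted 5-taxon modules."""
    config = SimConfig(seed=7)
    table, meta, truth = simulate_counts(config)
    return config, table, meta, truth


@pytest.fixture
def four_group_meta():
    meta = []
    for species, n in (("magnatum", 4), ("macrosporum", 3)):
        for compartment in ("surface", "gleba"):
            for rep in range(1, n + 1):
                meta.append(SampleMeta(
                    sample_id=f"{species[:3]}_{compartment}_{rep}",
                    species=species, compartment=compartment, replicate=rep,
                ))
    return meta


@pytest.fixture
def rng():
    return np.random.default_rng(20230801)
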