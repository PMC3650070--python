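import numpy as np
import pandas as pd
import pytest

import nucleoprof as npf
from nucleoprof import profile as prof

SIM_SEED = 0  # one fixed seed for every simulation-backed test


@pytest.fixture(scope="session")
def ordered_sim():
    cfg = npf.make_stage_config("ordered", seed=SIM_SEED)
    return npf.simulate_experiment(cfg)


@pytest.fixture(scope="session")
def ordered_result(ordered_sim):
    model = npf.NucleosomeProfile.from_tables(
        ordered_sim.probes, ordered_sim.signals, ordered_sim.tss
    )
    return model.fit()


@pytest.fixture(scope="session")
def hox_groups():
    return npf.io.load_hox_groups()


def make_rel_signals(entries) -> pd.DataFrame:
    """Build a TSS-relative record table from (gene_id, rel_pos, value) triples."""
    genes, pos, vals = zip(*entries)
    return pd.DataFrame(
        {
            "gene_id": genes,
            "probe_id": [f"p{i}" for i in range(len(genes))],
            "rel_pos": np.asarray(pos, float),
            "log2_ratio": np.asarray(vals, float),
        }
    )


@pytest.fixture
def rel_signals_factory():
    return make_rel_signals
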