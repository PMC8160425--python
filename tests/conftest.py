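import numpy as np
import pandas as pd
import pytest

import bcrclone as bc


@pytest.fixture(scope="session")
def reference():
    return bc.bundled_reference()


@pytest.fixture(scope="session")
def aligner():
    return bc.make_aligner()


@pytest.fixture(scope="session")
def small_sim(reference):
    """A small deterministic five-population repertoire with planted overlap."""
    cfg = bc.default_config(seed=42, n_clones=15)
    truth, table = bc.simulate_repertoire(cfg, reference)
    return cfg, truth, table


def make_rows(records):
    """Rearrangement frame from (sequence_id, population, v, j, cdr3, isotype,
    mutation_freq, duplicate_count) tuples."""
    return pd.DataFrame(
        records,
        columns=[
            "sequence_id", "population", "v_call", "j_call", "cdr3",
            "c_call", "mutation_freq", "duplicate_count",
        ],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
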