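import numpy as np
import pandas as pd
import pytest

from spliceomix.synthetic_data import (CohortDesign, EventDesign, SimConfig,
                                       JunctionCounts)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_config():
    """A fast simulation configuration shared across tests."""
    return SimConfig(
        seed=3, n_genes=8, exons_per_gene=(3, 5),
        event_design=[
            EventDesign("SE", 60, 0.5, 0.5),
            EventDesign("IR", 60, 0.5, 0.5),
            EventDesign("IR", 20, 0.3, 0.6),
        ],
        depth=100, n_replicates=3,
        cohort=CohortDesign(n_patients=60))


def make_counts(inc_a, skp_a, inc_b, skp_b):
    """Single-event count table with one replicate per group."""
    inc = pd.DataFrame({"A1": [inc_a], "B1": [inc_b]}, index=["EV1"])
    skp = pd.DataFrame({"A1": [skp_a], "B1": [skp_b]}, index=["EV1"])
    return JunctionCounts(inc, skp, pd.Series({"A1": "A", "B1": "B"}))
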