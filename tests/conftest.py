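import numpy as np
import pytest

import symmeta as sm


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_tip_tree():
    """((A:1,B:1):1,C:2); — shared depth 1 for A,B of total depth 2."""
    return sm.read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def small_dataset():
    """~25-record synthetic corpus with a 3-level moderator and phylogeny."""
    truth = sm.SimulationTruth(
        seed=7,
        n_studies=10,
        n_tips=8,
        beta0=0.5,
        moderator_effects={"mod": {"a": 0.0, "b": 1.0, "c": -0.5}},
    )
    df, tree, echo = sm.simulate_dataset(truth)
    return df, tree, truth
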