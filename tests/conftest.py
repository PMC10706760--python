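import numpy as np
import pytest

import techrono as tc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """A modest multi-class simulation shared by read-only tests."""
    cfg = tc.default_config(seed=7)
    return tc.simulate_genomes(cfg)


@pytest.fixture(scope="session")
def dating_sim():
    """Single large LTR family under constant insertion; used for recovery."""
    fams = [tc.FamilySpec("gypsy_big", "LTR", "gypsy", consensus_length=11500,
                          ltr_length=2500, rate_per_my=550)]
    cfg = tc.SimulationConfig(seed=11, families=fams, removal_half_life_my=3.0,
                              horizon_my=10.0, genome_length_bp=60_000_000)
    res = tc.simulate_genomes(cfg)
    ages = tc.date_all(res.ltr_pairs["g0"])
    truth = res.truth.set_index("copy_id")
    true_age = truth.loc[ages["element_id"], "age_years"].to_numpy()
    return res, ages, true_age
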