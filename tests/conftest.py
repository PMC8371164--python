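import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from hbfkit.simulate import Condition, SimConfig, simulate_genotypes

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")

#: two-deletion study panel: control + each partial deletion + both
DD_CONDITIONS = [
    Condition("AAVS1", single_guides=("AAVS1",)),
    Condition("HBB_HBD", paired_guides=("hbb_hbd",)),
    Condition("HBD_3p5kb", paired_guides=("hbd_3p5kb",)),
    Condition("BOTH", paired_guides=("hbb_hbd", "hbd_3p5kb")),
]


@pytest.fixture(scope="session")
def small_dataset():
    """One simulated colony cohort reused across read-only tests."""
    cfg = SimConfig(seed=11, colonies_per_condition=25)
    truth, alleles, junctions = simulate_genotypes(cfg)
    return cfg, truth, alleles, junctions


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


@pytest.fixture()
def balanced_oneway():
    """Balanced one-way random-intercept data: k=6 groups x m=10."""
    k, m = 6, 10
    gen = np.random.default_rng(77)
    groups = np.repeat(np.arange(k), m)
    y = 3.0 + gen.normal(0, 1.2, k)[groups] + gen.normal(0, 0.6, k * m)
    x = gen.normal(size=k * m)
    table = pd.DataFrame(
        {"y": y, "x": x, "grp": [f"g{i}" for i in groups]}
    )
    return k, m, table
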