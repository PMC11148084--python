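import numpy as np
import pandas as pd
import pytest

import saltscreen as ss


@pytest.fixture(scope="session")
def fixture_tables():
    """Published verification rows and model constants."""
    return ss.make_fixture_tables()


@pytest.fixture()
def small_table() -> pd.DataFrame:
    """2 genotypes x (control + 2 stress doses) x 6 traits x 2 replicates."""
    rows = []
    rng = np.random.default_rng(11)
    for g, rate in (("g1", 0.002), ("g2", 0.0028)):
        for t in ss.ALL_TRAITS:
            base = rng.uniform(2, 10)
            for c in (0.0, 150.0, 300.0):
                decline = 1.0 - rate * c
                for rep in (1, 2):
                    rows.append((g, c, rep, t, base * decline * (1 + 0.01 * rep)))
    return pd.DataFrame(rows, columns=["genotype", "concentration", "replicate",
                                       "trait", "value"])


@pytest.fixture(scope="session")
def zero_noise_pilot():
    """Deterministic pilot dataset (no saturation in the tested range)."""
    cfg = ss.pilot_config(random_seed=3, noise_cv=0.0,
                          concentrations=(0.0, 50.0, 100.0, 150.0),
                          tolerance_range=(0.3, 0.9))
    table, truth = ss.generate(cfg)
    return cfg, table, truth
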