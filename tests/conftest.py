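import numpy as np
import pandas as pd
import pytest

from dmscore.io import assay_from_frame
from dmscore.model import McmcConfig, ModelSpec, fit
from dmscore.preprocess import preprocess
from dmscore.simulate import SimConfig, simulate
from dmscore.substitution import build_groups


def toy_count_frame(T=2, R=2, variants=("A5V", "A5=", "K9R"), seed=0):
    """Small wide-format count table built in memory."""
    rng = np.random.default_rng(seed)
    data = {"variant": list(variants)}
    for t in range(T + 1):
        for r in range(1, R + 1):
            data[f"c_{t}_{r}"] = rng.integers(50, 500, size=len(variants))
    return pd.DataFrame(data)


@pytest.fixture
def toy_assay():
    return assay_from_frame(toy_count_frame())


@pytest.fixture(scope="session")
def default_sim():
    """The default-condition synthetic screen, preprocessed and grouped."""
    assay, truth = simulate(seed=1)
    assay = preprocess(assay)
    scheme = build_groups(assay)
    return assay, truth, scheme


@pytest.fixture(scope="session")
def default_fit(default_sim):
    """Full model fit on the default screen, shared across tests."""
    assay, truth, scheme = default_sim
    result = fit(assay, scheme, ModelSpec(3), McmcConfig(seed=1))
    return assay, truth, scheme, result


@pytest.fixture(scope="session")
def small_sim():
    """A 10-position screen for cheap fits."""
    cfg = SimConfig(n_positions=10)
    assay, truth = simulate(cfg, seed=3)
    assay = preprocess(assay)
    scheme = build_groups(assay)
    return assay, truth, scheme
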