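import numpy as np
import pandas as pd
import pytest

from sysgen.simulate import SimConfig, make_bundle


@pytest.fixture(scope="session")
def default_bundle():
    """The default synthetic bundle: 1000 genes, five 40-gene modules,
    200 samples, seed 7."""
    return make_bundle(SimConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_expr(rng):
    """Tiny random expression frame (8 genes x 30 samples)."""
    return pd.DataFrame(
        rng.standard_normal((8, 30)),
        index=[f"g{i}" for i in range(8)],
        columns=[f"s{j}" for j in range(30)],
    )
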