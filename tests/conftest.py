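import numpy as np
import pandas as pd
import pytest

from outliersuite.synthetic import generate, make_preset


@pytest.fixture(scope="session")
def clinical():
    """Seeded clinical-like dataset: 93 x 11, ~45% planted outliers."""
    matrix, meta, truth = generate(make_preset("clinical_like", seed=1))
    return matrix, meta, truth


@pytest.fixture(scope="session")
def invitro():
    """Seeded in-vitro-like dataset: 39 x 6, 5 planted outliers."""
    matrix, meta, truth = generate(make_preset("invitro_like", seed=1))
    return matrix, meta, truth


@pytest.fixture()
def small_matrix():
    rng = np.random.default_rng(7)
    return pd.DataFrame(
        rng.lognormal(size=(20, 4)),
        index=[f"S{i}" for i in range(20)],
        columns=list("abcd"),
    )
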