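import numpy as np
import pandas as pd
import pytest

from rtbimr.synthetic import CSIPhantomSpec


@pytest.fixture
def noiseless_spec():
    return CSIPhantomSpec(noise_sd=0.0)


@pytest.fixture
def default_spec():
    return CSIPhantomSpec()


def make_group_table(rng, n=20, p=44, d=0.0, planted=0):
    """Noise feature table with an optional planted group shift."""
    X = rng.normal(size=(n, p))
    groups = np.array(["Sham"] * (n // 2) + ["rTBI"] * (n - n // 2))
    X[groups == "rTBI", planted] += d
    df = pd.DataFrame(X, columns=[f"v{i}" for i in range(p)])
    df.insert(0, "group", groups)
    return df
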