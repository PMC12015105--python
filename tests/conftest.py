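import numpy as np
import pandas as pd
import pytest

import shumpanel as sp


def make_panel(Xneg, Xpos, markers, matrix_label="EV"):
    """Assemble a panel table from per-class feature matrices."""
    n0, n1 = len(Xneg), len(Xpos)
    df = pd.DataFrame(np.vstack([Xneg, Xpos]), columns=markers)
    df.insert(0, "matrix_label", matrix_label)
    df.insert(0, "class_label", ["PS"] * n0 + ["PR"] * n1)
    df.insert(0, "sample_id", [f"s{i:03d}" for i in range(n0 + n1)])
    return df


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_panel(rng):
    """Two markers, one informative: 20 + 20 samples."""
    Xn = rng.normal(0.0, 1.0, (20, 2))
    Xp = rng.normal([1.5, 0.0], 1.0, (20, 2))
    return make_panel(Xn, Xp, ["A", "B"])


@pytest.fixture
def separable_panel(rng):
    """Perfectly separated single informative marker."""
    Xn = np.column_stack([rng.uniform(0, 1, 15), rng.normal(0, 1, 15)])
    Xp = np.column_stack([rng.uniform(2, 3, 15), rng.normal(0, 1, 15)])
    return make_panel(Xn, Xp, ["A", "B"])


@pytest.fixture
def fast_config():
    return sp.SHUMConfig(restarts=3, seed=7)
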