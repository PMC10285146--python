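import numpy as np
import pytest

import overimpute as oi


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def incomplete_quadratic():
    """Small quadratic-outcome dataset with 30% MCAR missing y and the
    derived x^2 column."""
    df = oi.gen_quadratic_outcome(300, seed=42)
    spec = oi.AmputationSpec(["y"], 0.3, "MCAR")
    inc = oi.ampute(df, spec, rng=np.random.default_rng(43))
    frame = inc.to_dataframe()
    frame["x2"] = frame["x"] ** 2
    return oi.IncompleteDataset.from_dataframe(frame)


@pytest.fixture
def univariate_normal_incomplete():
    """One normal column with ~40% missing, as an IncompleteDataset."""
    gen = np.random.default_rng(99)
    y = gen.standard_normal(60)
    mask = gen.random(60) < 0.4
    vals = y.copy()
    vals[mask] = np.nan
    return oi.IncompleteDataset(
        vals[:, None], ~mask[:, None], ["y"], ["continuous"]
    )
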