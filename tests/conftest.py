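import numpy as np
import pandas as pd
import pytest

from gifa import synthetic


@pytest.fixture
def small_table() -> pd.DataFrame:
    """A tiny deterministic two-class case table (8 pos / 12 neg)."""
    spec = synthetic.FeatureTableSpec(
        n_pos=8, n_neg=12, n_features=4, n_informative=1, effect_size=2.0, seed=7
    )
    return synthetic.gen_feature_table(spec)


@pytest.fixture
def lung_phantom() -> synthetic.LabeledVolume:
    spec = synthetic.PhantomSpec(seed=3, shape=(24, 48, 48), noise_sd=10.0)
    return synthetic.gen_lung_volume(spec, emphysema_fraction=0.10)


@pytest.fixture
def abdominal_phantom() -> synthetic.LabeledVolume:
    spec = synthetic.PhantomSpec(seed=5, shape=(192, 192), noise_sd=8.0)
    return synthetic.gen_abdominal_slice(spec, sfa_area=6000.0, vfa_area=2500.0)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
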