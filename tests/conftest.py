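import numpy as np
import pandas as pd
import pytest

from phrelay.containers import FeatureTrajectory


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_feature_traj(values, names=None, interval=1.0, replica="0",
                      ensemble=None):
    """1-D input is one feature over frames; 2-D is frames x features."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if names is None:
        names = [f"f{i}" for i in range(values.shape[1])]
    return FeatureTrajectory(pd.DataFrame(values, columns=names), interval,
                             replica, ensemble)
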