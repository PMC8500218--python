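import numpy as np
import pandas as pd
import pytest

from motionrca.epochs import EpochSet
from motionrca.montage import hydrocel_128


@pytest.fixture(scope="session")
def montage():
    return hydrocel_128()


def make_epochs(data, mask=None, time0_ms=-100.0, sfreq=500.0, trials=None,
                channels=None):
    """Build a minimal EpochSet around a (trials, channels, samples) array."""
    data = np.asarray(data, dtype=float)
    n_t, n_c, n_s = data.shape
    if channels is None:
        channels = np.arange(1, n_c + 1)
    if trials is None:
        trials = pd.DataFrame({"trial": np.arange(n_t)})
    time_ms = time0_ms + np.arange(n_s) * 1000.0 / sfreq
    return EpochSet(data=data, mask=mask, time_ms=time_ms, channels=channels,
                    trials=trials, sfreq=sfreq)
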