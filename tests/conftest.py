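import numpy as np
import pytest
from hypothesis import settings

import tftseg as T

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def montage():
    return T.default_montage()


@pytest.fixture(scope="session")
def blink_run():
    """One blink-fixture recording taken through bandpass + ICA + features."""
    rec, gt = T.simulate_eeg(T.simulate.blink_fixture_config(seed=7))
    filt = T.bandpass(rec)
    dec = T.ica_fit(filt, seed=7)
    feats = T.adjust_features(dec)
    flags = T.flag_artifacts(feats, seed=7)
    return {"rec": rec, "gt": gt, "filt": filt, "dec": dec,
            "feats": feats, "flags": flags}


@pytest.fixture(scope="session")
def four_regime_run():
    """Four-regime recording through the full segmentation stage."""
    rec, gt = T.simulate_eeg(T.four_regime_config(seed=11))
    filt = T.bandpass(rec)
    tensor = T.compute_tft(filt)
    X = T.tft_features(tensor)
    lab = T.constrained_hca(X, time_axis=tensor.time_axis,
                            duration=tensor.duration)
    return {"rec": rec, "gt": gt, "filt": filt, "tensor": tensor,
            "features": X, "labeling": lab}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
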