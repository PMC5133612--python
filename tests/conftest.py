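import numpy as np
import pytest

import panthoot as ph


def featurize(recordings, phases=None):
    """MFCC+delta features for every (call, phase) clip of interest."""
    feats = {}
    for rec in recordings:
        for phase in rec.phases_present():
            if phases is not None and phase not in phases:
                continue
            cid = f"{rec.call_id}:{phase}"
            feats[cid] = ph.extract_features(
                rec.phase_waveform(phase), rec.sample_rate_hz, clip_id=cid
            )
    return feats


@pytest.fixture(scope="session")
def population10():
    return ph.make_population(10, seed=1)


@pytest.fixture(scope="session")
def null_climax_dataset(population10):
    """60 calls with all effect sizes zero; climax features only."""
    recs, meta = ph.make_dataset(
        population10, 60, effects=ph.EffectConfig.null(), seed=2
    )
    return featurize(recs, phases=("climax",)), meta


@pytest.fixture(scope="session")
def toy_blobs():
    """Two well-separated 2-D Gaussian clouds (linearly separable)."""
    rng = np.random.default_rng(3)
    a = rng.normal(loc=(-3.0, -3.0), scale=0.4, size=(20, 2))
    b = rng.normal(loc=(3.0, 3.0), scale=0.4, size=(20, 2))
    X = np.vstack([a, b])
    y = np.array([0] * 20 + [1] * 20)
    return X, y
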