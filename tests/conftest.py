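import dataclasses

import numpy as np
import pytest

from splitbeat import anomaly, dataset as dio, model as mdl, synthetic as syn


@pytest.fixture(scope="session")
def quiet_template():
    """Default morphology with the default 3%-of-R noise level."""
    return syn.DEFAULT_TEMPLATE


@pytest.fixture(scope="session")
def noiseless_template():
    return dataclasses.replace(syn.DEFAULT_TEMPLATE, noise_sd=0.0)


@pytest.fixture(scope="session")
def small_trained():
    """A small but genuinely trained detector on 500 synthetic normals.

    Session-scoped: training is sub-second but shared by many tests. Returns
    (detector, prepared normal test set, normalization).
    """
    train_ds = syn.make_dataset(500, 0, [], syn.DEFAULT_TEMPLATE, seed=11)
    test_ds = syn.make_dataset(80, 0, [], syn.DEFAULT_TEMPLATE, seed=12)
    lo, hi = dio.fit_normalization(train_ds)
    train_n = dio.apply_normalization(train_ds, lo, hi)
    test_n = dio.apply_normalization(test_ds, lo, hi)
    model = mdl.build_model(init_seed=3)
    model, _ = mdl.train(model, train_n, None, epochs=40, seed=3)
    detector = anomaly.fit_threshold(model, train_n, k=1.0)
    return detector, test_n, (lo, hi)


@pytest.fixture(scope="session")
def constant_beat_dataset():
    """140-point beats all identically 0.5, stamped with identity normalization."""
    rec = dio.BeatRecord(label=1, samples=np.full(140, 0.5))
    ds = dio.BeatDataset(records=[rec] * 32, length=140)
    return dio.apply_normalization(ds, 0.0, 1.0)
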