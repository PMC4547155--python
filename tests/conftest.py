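import numpy as np
import pytest

import harkit as hk


@pytest.fixture
def default_layout():
    return hk.mhealth_default_layout()


@pytest.fixture
def toy_session(default_layout):
    """Three samples in the full 23-channel layout, labels 1, 1, 2."""
    n_channels = sum(len(s.axes) for d in default_layout for s in d.sensors)
    meta = hk.Metadata(
        session_id="toy",
        subject_id="s1",
        start_time=0.0,
        end_time=2 / 50.0,
        sampling_rate=50.0,
        devices=default_layout,
    )
    samples = tuple(
        hk.Sample(i / 50.0, tuple(float(i * n_channels + j) for j in range(n_channels)), label)
        for i, label in enumerate((1, 1, 2))
    )
    return hk.Session(meta, samples)


@pytest.fixture(scope="session")
def small_dataset():
    """Two short synthetic subjects shared across tests (10 s/activity)."""
    return hk.generate_dataset(2, hk.default_schedule(10.0), seed=42)


@pytest.fixture(scope="session")
def small_features(small_dataset):
    return hk.sessions_to_features(small_dataset)
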