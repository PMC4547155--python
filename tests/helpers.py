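"""Shared test utilities."""

import numpy as np

import harkit as hk


def make_matrix(values, labels, rate=50.0, names=None):
    values = np.asarray(values, dtype=float)
    if values.ndim == 1:
        values = values[:, None]
    if names is None:
        names = tuple(f"ch{i}" for i in range(values.shape[1]))
    return hk.ChannelMatrix(names, values, np.asarray(labels, dtype=np.int64), rate)
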