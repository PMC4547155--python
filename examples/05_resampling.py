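"""Sampling-rate adjustment: decimation and linear-interpolation upsampling.

Downsampling keeps every k-th row (no filtering); upsampling inserts
k-1 linearly interpolated rows per gap.  Composing the two converts
between rational rates, and downsample(upsample(x, k), k) returns x
exactly.
"""

import numpy as np

import harkit as hk

matrix = hk.ChannelMatrix(
    ("acc/x",),
    np.array([[0.0], [1.0], [4.0], [9.0]]),
    np.array([1, 1, 2, 2]),
    sampling_rate=50.0,
)

up = hk.upsample(matrix, 2)
print(f"upsampled to {up.sampling_rate:g} Hz: {up.values[:, 0].tolist()}")
print(f"labels follow the left neighbour: {up.labels.tolist()}")

down = hk.downsample(up, 2)
print(f"decimated back to {down.sampling_rate:g} Hz: {down.values[:, 0].tolist()}")
assert np.array_equal(down.values, matrix.values)
# The midpoints (0.5, 2.5, 6.5) are linear interpolations; decimation
# recovers the original rows bit-for-bit.
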