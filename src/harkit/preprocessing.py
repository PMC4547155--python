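"""Sampling-rate adjustment for channel matrices.

Two complementary operations: integer-factor decimation (keep every
k-th row, no anti-alias filter) and integer-factor upsampling by linear
interpolation.  Rational rate conversion is obtained by composing the
two.  Labels are carried along: decimation keeps the label of each kept
row; upsampling copies the left neighbour's label onto inserted rows,
so the label stream never acquires codes absent from the input.
"""

from __future__ import annotations

import numpy as np

from .data_model import ChannelMatrix

__all__ = ["downsample", "upsample"]


def _check_factor(factor) -> int:
    if isinstance(factor, bool) or not isinstance(factor, (int, np.integer)):
        raise ValueError(f"factor must be a positive integer, got {factor!r}")
    if factor < 1:
        raise ValueError(f"factor must be >= 1, got {factor}")
    return int(factor)


def downsample(matrix: ChannelMatrix, factor) -> ChannelMatrix:
    """Keep rows 0, factor, 2*factor, ... and divide the rate by factor.

    Plain decimation without filtering — deterministic and exactly
    invertible by :func:`upsample` at the kept rows.
    """
    factor = _check_factor(factor)
    if matrix.n_samples == 0:
        raise ValueError("cannot downsample an empty matrix")
    return ChannelMatrix(
        channel_names=matrix.channel_names,
        values=matrix.values[::factor].copy(),
        labels=matrix.labels[::factor].copy(),
        sampling_rate=matrix.sampling_rate / factor,
    )


def upsample(matrix: ChannelMatrix, factor) -> ChannelMatrix:
    """Insert ``factor - 1`` linearly interpolated rows between neighbours.

    Output length is ``(N - 1) * factor + 1``; the first and last rows
    are preserved bit-for-bit, and interpolation is exact on affine
    sequences.  Inserted rows take the label of their left neighbour.
    """
    factor = _check_factor(factor)
    n = matrix.n_samples
    if factor == 1:
        return ChannelMatrix(
            channel_names=matrix.channel_names,
            values=matrix.values.copy(),
            labels=matrix.labels.copy(),
            sampling_rate=matrix.sampling_rate,
        )
    if n < 2:
        raise ValueError("upsampling with factor > 1 requires at least 2 rows")

    out_n = (n - 1) * factor + 1
    pos = np.arange(out_n) / factor
    lo = np.floor(pos).astype(np.int64)
    hi = np.minimum(lo + 1, n - 1)
    w = (pos - lo)[:, None]
    # w == 0 exactly at original grid points, so those rows pass through
    # unchanged.
    values = (1.0 - w) * matrix.values[lo] + w * matrix.values[hi]
    labels = matrix.labels[lo]
    return ChannelMatrix(
        channel_names=matrix.channel_names,
        values=values,
        labels=labels,
        sampling_rate=matrix.sampling_rate * factor,
    )
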