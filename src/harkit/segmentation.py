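"""Fixed-duration windowing of continuous sensor streams.

The recognition pipeline tiles a stream into non-overlapping windows of
``window_seconds`` (default 2 s, i.e. 100 samples at 50 Hz).  Each
window records its sample-index extent, its end time, the majority
activity label of its rows, the fraction of rows carrying that label
(purity) and whether the window straddles a label change
(``is_transition``, purity < 1).

Batch (:func:`make_windows`) and streaming (:class:`StreamSegmenter`)
segmentation are guaranteed to produce identical windows on identical
data, so an online recognizer can be validated against its offline
counterpart.

A window-end prediction refers to activity that happened over the whole
window, i.e. on average ``window_seconds / 2`` earlier;
:func:`segmentation_delay` exposes that offset explicitly so evaluation
code aligns predictions with ground truth deliberately rather than
implicitly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_model import ChannelMatrix, Sample

__all__ = ["Window", "make_windows", "StreamSegmenter", "stream_push", "segmentation_delay"]


@dataclass
class Window:
    """A contiguous fixed-length segment with its majority label."""

    values: np.ndarray  # (n x channels)
    channel_names: tuple[str, ...]
    start_index: int
    end_index: int  # half-open [start_index, end_index)
    end_time: float  # seconds; end_index / sampling_rate
    label: int
    purity: float
    is_transition: bool

    @property
    def n_samples(self) -> int:
        return self.end_index - self.start_index


def _majority_label(labels: np.ndarray) -> tuple[int, float]:
    """Majority label and its frequency; ties break toward the first row's
    label, else the smallest code (deterministic)."""
    counts = np.bincount(labels)
    top = counts.max()
    candidates = np.flatnonzero(counts == top)
    first = labels[0]
    label = int(first) if first in candidates else int(candidates[0])
    return label, top / len(labels)


def make_windows(
    matrix: ChannelMatrix,
    window_seconds: float,
    stride: int | None = None,
) -> list[Window]:
    """Tile a channel matrix into fixed-length windows.

    The window length is ``n = floor(window_seconds * sampling_rate)``
    samples; a trailing partial window is discarded.  ``stride`` (in
    samples) defaults to ``n`` — non-overlapping tiling; smaller strides
    give overlapping windows.
    """
    n = int(math.floor(window_seconds * matrix.sampling_rate + 1e-9))
    if n < 1:
        raise ValueError(
            f"window of {window_seconds} s at {matrix.sampling_rate} Hz holds no samples"
        )
    if stride is None:
        stride = n
    if stride < 1:
        raise ValueError("stride must be >= 1")
    rows = matrix.n_samples
    windows: list[Window] = []
    for start in range(0, rows - n + 1, stride):
        end = start + n
        labels = matrix.labels[start:end]
        label, purity = _majority_label(labels)
        windows.append(
            Window(
                values=matrix.values[start:end],
                channel_names=matrix.channel_names,
                start_index=start,
                end_index=end,
                end_time=end / matrix.sampling_rate,
                label=label,
                purity=purity,
                is_transition=purity < 1.0,
            )
        )
    return windows


class StreamSegmenter:
    """Incremental windowing for sample-at-a-time (online) processing.

    Buffers pushed rows and emits a :class:`Window` exactly when the
    n-th one arrives, then starts a fresh buffer.  The emitted windows
    are identical to what :func:`make_windows` produces on the
    concatenated stream (non-overlapping tiling only).
    """

    def __init__(
        self,
        channel_names: tuple[str, ...],
        window_seconds: float,
        sampling_rate: float,
    ) -> None:
        self.channel_names = tuple(channel_names)
        self.sampling_rate = float(sampling_rate)
        self.window_length = int(math.floor(window_seconds * sampling_rate + 1e-9))
        if self.window_length < 1:
            raise ValueError("window holds no samples at this rate")
        self._values: list[np.ndarray] = []
        self._labels: list[int] = []
        self._consumed = 0  # total rows pushed, for global indices

    @property
    def pending(self) -> int:
        """Rows buffered toward the next window."""
        return len(self._values)

    def push(self, values, label: int) -> Window | None:
        """Add one row; return a Window when the buffer fills, else None."""
        row = np.asarray(values, dtype=np.float64)
        if row.shape != (len(self.channel_names),):
            raise ValueError(
                f"expected {len(self.channel_names)} channel values, got shape {row.shape}"
            )
        self._values.append(row)
        self._labels.append(int(label))
        self._consumed += 1
        if len(self._values) < self.window_length:
            return None
        end = self._consumed
        start = end - self.window_length
        labels = np.asarray(self._labels, dtype=np.int64)
        label_, purity = _majority_label(labels)
        window = Window(
            values=np.vstack(self._values),
            channel_names=self.channel_names,
            start_index=start,
            end_index=end,
            end_time=end / self.sampling_rate,
            label=label_,
            purity=purity,
            is_transition=purity < 1.0,
        )
        self._values.clear()
        self._labels.clear()
        return window


def stream_push(state: StreamSegmenter, sample: Sample) -> Window | None:
    """Push a :class:`~harkit.data_model.Sample` into a streaming buffer."""
    return state.push(sample.values, sample.label)


def segmentation_delay(window_seconds: float) -> float:
    """Offset between a window-end prediction and the activity's centre.

    A prediction issued when a window closes describes, on average, the
    activity half a window earlier; with the standard 2-s window this is
    the 1-second segmentation delay that online evaluation must undo
    when aligning predictions with ground truth.
    """
    if window_seconds <= 0:
        raise ValueError("window_seconds must be positive")
    return window_seconds / 2.0
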