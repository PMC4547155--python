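"""Per-window, per-channel time-domain statistics.

Seven statistics are available: mean, variance, standard deviation
(sample convention, N-1 denominator), maximum, minimum, zero-crossing
count (zcr) and mean-crossing count (mcr).

Crossing counts need a sign convention for exact zeros: a zero sample
inherits the most recent nonzero sign, and leading zeros count as
positive.  So ``[1, 0, -1]`` has one crossing (the zero belongs to the
positive run), and a constant window has zcr = mcr = 0.  mcr is simply
zcr of the mean-centred signal.

The recognition model's default feature set is {mean, std, max, min}
over the 9 acceleration channels, i.e. 36 features per 2-s window; the
remaining statistics are available for library users.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .segmentation import Window

__all__ = [
    "STATISTICS",
    "DEFAULT_STATISTICS",
    "FeatureMatrix",
    "window_statistic",
    "extract_features",
]

STATISTICS = ("mean", "variance", "std", "max", "min", "zcr", "mcr")

#: Feature set of the default activity-recognition model.
DEFAULT_STATISTICS = ("mean", "std", "max", "min")


@dataclass
class FeatureMatrix:
    """Windows x features table with per-window labels.

    Feature names are ``channel:statistic`` (outer loop over channels,
    inner loop over statistics).
    """

    feature_names: tuple[str, ...]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.feature_names = tuple(self.feature_names)
        self.values = np.asarray(self.values, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (windows x features)")
        if self.values.shape[0] != self.labels.shape[0]:
            raise ValueError("values and labels disagree on row count")
        if self.values.shape[1] != len(self.feature_names):
            raise ValueError("values and feature_names disagree on column count")

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, rows) -> "FeatureMatrix":
        return FeatureMatrix(self.feature_names, self.values[rows], self.labels[rows])

    def to_csv(self, path) -> None:
        """Write as headered CSV, label column last."""
        frame = pd.DataFrame(self.values, columns=list(self.feature_names))
        frame["label"] = self.labels
        frame.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "FeatureMatrix":
        frame = pd.read_csv(path)
        if "label" not in frame.columns:
            raise ValueError(f"{path}: feature CSV lacks a 'label' column")
        labels = frame.pop("label").to_numpy(dtype=np.int64)
        return cls(tuple(frame.columns), frame.to_numpy(dtype=np.float64), labels)


def _inherited_signs(x: np.ndarray) -> np.ndarray:
    """Signs along the last axis, zeros inheriting the previous nonzero
    sign; leading zeros count positive."""
    s = np.sign(x)
    nz = s != 0
    idx = np.where(nz, np.arange(x.shape[-1]), -1)
    idx = np.maximum.accumulate(idx, axis=-1)
    filled = np.where(idx >= 0, np.take_along_axis(s, np.maximum(idx, 0), axis=-1), 1.0)
    return filled


def _crossings(x: np.ndarray) -> np.ndarray:
    s = _inherited_signs(x)
    return np.count_nonzero(s[..., 1:] != s[..., :-1], axis=-1)


def window_statistic(x: Sequence[float], statistic: str) -> float:
    """Compute a single named statistic of a 1-D sample sequence.

    variance/std use the N-1 denominator and require at least two
    samples; all statistics require a non-empty input.
    """
    arr = np.asarray(x, dtype=np.float64)
    if arr.ndim != 1:
        raise ValueError("window_statistic expects a 1-D sequence")
    if arr.size == 0:
        raise ValueError("empty input")
    if statistic == "mean":
        return float(arr.mean())
    if statistic in ("variance", "std"):
        if arr.size < 2:
            raise ValueError(f"{statistic} requires at least 2 samples")
        var = float(arr.var(ddof=1))
        return var if statistic == "variance" else float(np.sqrt(var))
    if statistic == "max":
        return float(arr.max())
    if statistic == "min":
        return float(arr.min())
    if statistic == "zcr":
        return float(_crossings(arr))
    if statistic == "mcr":
        return float(_crossings(arr - arr.mean()))
    raise ValueError(f"unknown statistic {statistic!r}")


def extract_features(
    windows: Sequence[Window],
    channels: Sequence[str] | None = None,
    statistics: Sequence[str] = DEFAULT_STATISTICS,
) -> FeatureMatrix:
    """Build the windows x (channels * statistics) feature table.

    ``channels`` defaults to every channel of the windows; all windows
    must share one channel layout and length.  Column order is channel-
    major: for each channel, the selected statistics in order.  Window
    labels are copied through.
    """
    statistics = tuple(statistics)
    if not statistics:
        raise ValueError("statistics must be non-empty")
    for stat in statistics:
        if stat not in STATISTICS:
            raise ValueError(f"unknown statistic {stat!r}; choose from {STATISTICS}")
    if not windows:
        names = tuple(
            f"{ch}:{st}" for ch in (channels or ()) for st in statistics
        )
        return FeatureMatrix(names, np.empty((0, len(names))), np.empty(0, dtype=np.int64))

    layout = windows[0].channel_names
    for w in windows:
        if w.channel_names != layout:
            raise ValueError("windows do not share a channel layout")
    if channels is None:
        channels = layout
    col_of = {name: i for i, name in enumerate(layout)}
    try:
        cols = [col_of[ch] for ch in channels]
    except KeyError as exc:
        raise ValueError(f"channel {exc.args[0]!r} not present in windows") from None

    # (windows x n x selected-channels) stack; windows from the tiling
    # segmenter share n by construction.
    stack = np.stack([w.values[:, cols] for w in windows])  # W x n x C
    per_stat: dict[str, np.ndarray] = {}
    for stat in set(statistics):
        if stat == "mean":
            per_stat[stat] = stack.mean(axis=1)
        elif stat == "variance":
            per_stat[stat] = stack.var(axis=1, ddof=1)
        elif stat == "std":
            per_stat[stat] = stack.std(axis=1, ddof=1)
        elif stat == "max":
            per_stat[stat] = stack.max(axis=1)
        elif stat == "min":
            per_stat[stat] = stack.min(axis=1)
        elif stat == "zcr":
            per_stat[stat] = _crossings(np.swapaxes(stack, 1, 2)).astype(np.float64)
        elif stat == "mcr":
            centred = stack - stack.mean(axis=1, keepdims=True)
            per_stat[stat] = _crossings(np.swapaxes(centred, 1, 2)).astype(np.float64)

    n_ch, n_st = len(channels), len(statistics)
    out = np.empty((len(windows), n_ch * n_st))
    names = []
    for c, ch in enumerate(channels):
        for s, stat in enumerate(statistics):
            out[:, c * n_st + s] = per_stat[stat][:, c]
            names.append(f"{ch}:{stat}")
    labels = np.array([w.label for w in windows], dtype=np.int64)
    return FeatureMatrix(tuple(names), out, labels)
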