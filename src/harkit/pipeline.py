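"""Convenience wiring of the full recognition chain.

These helpers connect the stage modules with the defaults of the
standard activity-recognition model: the 9 acceleration channels,
2-second non-overlapping windows and the {mean, std, max, min} feature
set.  They exist so scripts, the CLI and the examples do not repeat the
same plumbing; every step remains available individually.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_model import ChannelMatrix, Session, acceleration_channels, select_channels
from .features import DEFAULT_STATISTICS, FeatureMatrix, extract_features
from .segmentation import StreamSegmenter, make_windows

__all__ = ["session_matrix", "session_features", "sessions_to_features", "stream_predict"]

WINDOW_SECONDS = 2.0


def session_matrix(session: Session, channels: Sequence[str] | None = None) -> ChannelMatrix:
    """Select the recognition channels (default: all accelerometers)."""
    if channels is None:
        channels = acceleration_channels(session.metadata)
    return select_channels(session, channels)


def session_features(
    session: Session,
    window_seconds: float = WINDOW_SECONDS,
    statistics: Sequence[str] = DEFAULT_STATISTICS,
    channels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Session -> windows -> feature matrix with the model defaults."""
    matrix = session_matrix(session, channels)
    windows = make_windows(matrix, window_seconds)
    return extract_features(windows, statistics=statistics)


def sessions_to_features(
    sessions: Sequence[Session],
    window_seconds: float = WINDOW_SECONDS,
    statistics: Sequence[str] = DEFAULT_STATISTICS,
    channels: Sequence[str] | None = None,
) -> FeatureMatrix:
    """Pool per-session feature matrices into one training table."""
    parts = [
        session_features(s, window_seconds, statistics, channels) for s in sessions
    ]
    names = parts[0].feature_names
    for p in parts[1:]:
        if p.feature_names != names:
            raise ValueError("sessions produced different feature layouts")
    return FeatureMatrix(
        names,
        np.vstack([p.values for p in parts]),
        np.concatenate([p.labels for p in parts]),
    )


def stream_predict(
    session: Session,
    model,
    window_seconds: float = WINDOW_SECONDS,
    statistics: Sequence[str] = DEFAULT_STATISTICS,
    channels: Sequence[str] | None = None,
) -> list[tuple[float, int]]:
    """Replay a session sample-by-sample and emit (end_time, label) pairs.

    Uses the streaming segmenter, so this is exactly what an online
    recognizer would produce on the same data; by construction it
    matches batch windowing + prediction.
    """
    from .classification import predict_values  # local to avoid cycle at import

    matrix = session_matrix(session, channels)
    segmenter = StreamSegmenter(
        matrix.channel_names, window_seconds, matrix.sampling_rate
    )
    out: list[tuple[float, int]] = []
    for i in range(matrix.n_samples):
        window = segmenter.push(matrix.values[i], int(matrix.labels[i]))
        if window is None:
            continue
        fm = extract_features([window], statistics=statistics)
        label = int(predict_values(model, fm.values)[0])
        out.append((window.end_time, label))
    return out
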