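"""Non-overlapping window segmentation and five-statistic aggregation.

Each of the 67 feature streams is cut into consecutive, non-overlapping
windows and summarized by five *window types*: mean, minimum, maximum,
range, standard deviation. The resulting window vector always has
67 x 5 = 335 dimensions regardless of window length.

Window lengths are given in seconds, or the token ``"session"`` for a single
window spanning the whole recording (the study's sessions last about
2.5 min). A trailing remainder shorter than the window is dropped. Movement
streams (defined on frame transitions) are assigned to the window containing
the later frame of each pair, so window boundaries are unambiguous.

The standard deviation uses the n-1 (sample) denominator, matching the
classifier's sample estimates; ``ddof=0`` is available via ``aggregate``'s
``ddof`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import FeatureStreams, N_FEATURES

WINDOW_TYPES = ("mean", "minimum", "maximum", "range", "standard_deviation")
SESSION_WINDOW = "session"

#: the study's window lengths, seconds (plus the whole-session token)
DEFAULT_WINDOW_LENGTHS = (SESSION_WINDOW, 60, 30, 10, 5, 1)

N_DIMS = N_FEATURES * len(WINDOW_TYPES)  # 335


def column_names(catalogue) -> list[str]:
    """The 335 canonical column names, ``<feature_id>__<window_type>``."""
    return [f"{d.feature_id}__{w}" for d in catalogue for w in WINDOW_TYPES]


@dataclass
class WindowSlice:
    """Raw stream samples of one window: pose ``(n, 37)``, movement ``(m, 30)``."""

    pose: np.ndarray
    movement: np.ndarray
    window_index: int


@dataclass
class WindowVector:
    """A 335-dimensional aggregated feature vector with window metadata."""

    values: np.ndarray  # (335,)
    window_length: float | str
    window_index: int
    interviewee_id: str = ""
    session_kind: str = ""
    condition: str = "unknown"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_DIMS,):
            raise ValueError(f"window vector must have {N_DIMS} values")


def segment(streams: FeatureStreams, window_length: float | str) -> list[WindowSlice]:
    """Cut feature streams into non-overlapping windows.

    ``window_length`` is in seconds or ``"session"`` for one whole-recording
    window. Remainder frames that do not fill a window are dropped.
    """
    T = streams.n_frames
    if window_length == SESSION_WINDOW:
        return [WindowSlice(pose=streams.pose, movement=streams.movement, window_index=0)]
    w = int(round(float(window_length) * streams.sample_rate_hz))
    if abs(w - float(window_length) * streams.sample_rate_hz) > 1e-9:
        raise ValueError(
            f"window of {window_length} s is not a whole number of samples "
            f"at {streams.sample_rate_hz} Hz"
        )
    if w < 2:
        raise ValueError(
            f"window of {window_length} s holds fewer than 2 samples "
            f"at {streams.sample_rate_hz} Hz"
        )
    n_windows = T // w
    out: list[WindowSlice] = []
    for k in range(n_windows):
        lo, hi = k * w, (k + 1) * w
        # movement sample i sits between frames i and i+1; it belongs to the
        # window containing frame i+1
        mlo, mhi = max(lo - 1, 0), hi - 1
        out.append(
            WindowSlice(
                pose=streams.pose[lo:hi],
                movement=streams.movement[mlo:mhi],
                window_index=k,
            )
        )
    return out


def aggregate(window: WindowSlice, ddof: int = 1) -> np.ndarray:
    """Five statistics per feature, flattened to the canonical 335 vector.

    Order is feature-major: for each catalogue feature, (mean, minimum,
    maximum, range, standard_deviation).
    """
    if window.pose.shape[0] < 2 or window.movement.shape[0] < 2:
        raise ValueError("aggregation needs at least 2 samples per feature")
    stats = np.empty((N_FEATURES, len(WINDOW_TYPES)))
    for block, cols in ((window.movement, slice(0, 30)), (window.pose, slice(30, 67))):
        stats[cols, 0] = block.mean(axis=0)
        stats[cols, 1] = block.min(axis=0)
        stats[cols, 2] = block.max(axis=0)
        stats[cols, 3] = stats[cols, 2] - stats[cols, 1]
        stats[cols, 4] = block.std(axis=0, ddof=ddof)
    return stats.reshape(-1)


def window_vectors(
    streams: FeatureStreams,
    window_length: float | str,
    *,
    interviewee_id: str = "",
    session_kind: str = "",
    condition: str = "unknown",
    ddof: int = 1,
) -> list[WindowVector]:
    """Segment and aggregate one session's streams into window vectors."""
    return [
        WindowVector(
            values=aggregate(ws, ddof=ddof),
            window_length=window_length,
            window_index=ws.window_index,
            interviewee_id=interviewee_id,
            session_kind=session_kind,
            condition=condition,
        )
        for ws in segment(streams, window_length)
    ]
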