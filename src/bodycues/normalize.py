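"""Spatial and temporal normalization of motion-capture sessions.

Three steps, applied in a fixed order:

1. :func:`resample` — decimate from the capture rate (60 Hz) down to 5 Hz,
   keeping every ``rate/target``-th frame. Decimation preserves instantaneous
   poses; frame averaging is available via ``method="mean"``.
2. :func:`center_on_root` — express every joint relative to the same-frame
   pelvis, removing global position. The pelvis itself is dropped, leaving a
   66-dimensional pose (22 joints x 3).
3. :func:`scale_segments` — rebuild the kinematic tree with every segment set
   to a corpus-average reference length, removing differences in body
   dimensions while preserving segment directions.

All three commute for the features computed downstream (which depend only on
body-relative distances and angles); the order above is fixed for
reproducibility.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ZeroLengthSegmentError
from .io import MocapSession
from .skeleton import Skeleton, default_skeleton

DEFAULT_TARGET_HZ = 5.0


def resample(
    session: MocapSession, target_hz: float, method: str = "decimate"
) -> MocapSession:
    """Downsample a session to ``target_hz``.

    ``method="decimate"`` (default) keeps every k-th frame starting at frame
    0; ``method="mean"`` averages each block of k frames (trailing partial
    block dropped). The source rate must be an integer multiple of the
    target rate.
    """
    ratio = session.sample_rate_hz / target_hz
    if abs(ratio - round(ratio)) > 1e-9 or ratio < 1:
        raise ValueError(
            f"sample rate {session.sample_rate_hz} Hz is not an integer "
            f"multiple of target {target_hz} Hz"
        )
    step = int(round(ratio))
    if step == 1:
        return session
    if method == "decimate":
        frames = session.frames[::step]
    elif method == "mean":
        n = session.n_frames // step
        frames = session.frames[: n * step].reshape(n, step, 23, 3).mean(axis=1)
    else:
        raise ValueError(f"unknown resampling method {method!r}")
    return session.with_frames(frames, sample_rate_hz=target_hz)


def center_on_root(
    frames: np.ndarray, skeleton: Skeleton | None = None
) -> np.ndarray:
    """Subtract the same-frame pelvis from every joint; drop the pelvis.

    Parameters
    ----------
    frames
        ``(T, 23, 3)`` absolute joint positions.

    Returns
    -------
    ``(T, 22, 3)`` root-relative positions of the non-root joints, in
    canonical order.
    """
    skeleton = skeleton or default_skeleton()
    frames = np.asarray(frames, dtype=float)
    root_idx = skeleton.index[skeleton.root]
    rel = frames - frames[:, root_idx : root_idx + 1, :]
    keep = [skeleton.index[j] for j in skeleton.non_root_joints]
    return rel[:, keep, :]


@dataclass(frozen=True)
class ReferenceLengths:
    """Average parent-child segment lengths (meters), one per segment.

    ``lengths[child]`` is the reference length of the segment ending at
    ``child``, for each of the 22 non-root joints.
    """

    lengths: dict[str, float]

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.lengths.values()):
            raise ValueError("all reference lengths must be strictly positive")

    def as_array(self, skeleton: Skeleton) -> np.ndarray:
        return np.array([self.lengths[j] for j in skeleton.non_root_joints])


def segment_lengths(frames: np.ndarray, skeleton: Skeleton | None = None) -> np.ndarray:
    """Per-frame parent-child distances, shape ``(T, 22)`` in canonical child order."""
    skeleton = skeleton or default_skeleton()
    frames = np.asarray(frames, dtype=float)
    out = np.empty((frames.shape[0], 22))
    for k, (par, child) in enumerate(skeleton.segments):
        d = frames[:, skeleton.index[child], :] - frames[:, skeleton.index[par], :]
        out[:, k] = np.linalg.norm(d, axis=1)
    return out


def compute_reference_lengths(
    corpus: list[MocapSession], skeleton: Skeleton | None = None
) -> ReferenceLengths:
    """Mean parent-child distance per segment over all frames of all sessions."""
    if not corpus:
        raise ValueError("cannot compute reference lengths from an empty corpus")
    skeleton = skeleton or default_skeleton()
    total = np.zeros(22)
    n = 0
    for session in corpus:
        sl = segment_lengths(session.frames, skeleton)
        total += sl.sum(axis=0)
        n += sl.shape[0]
    mean = total / n
    return ReferenceLengths(
        {child: float(mean[k]) for k, (_, child) in enumerate(skeleton.segments)}
    )


def scale_segments(
    relative_frames: np.ndarray,
    reference: ReferenceLengths,
    skeleton: Skeleton | None = None,
) -> np.ndarray:
    """Rescale every segment of centered frames to its reference length.

    The tree is rebuilt from the root outward: each joint is placed at its
    (rebuilt) parent's position plus the original unit parent-to-joint
    direction times the reference length. Output segment lengths therefore
    equal the reference lengths exactly (to floating tolerance).

    Raises
    ------
    ZeroLengthSegmentError
        If any original segment has zero length (direction undefined).
    """
    skeleton = skeleton or default_skeleton()
    rel = np.asarray(relative_frames, dtype=float)
    if rel.ndim != 3 or rel.shape[1:] != (22, 3):
        raise ValueError(f"expected centered frames of shape (T, 22, 3), got {rel.shape}")
    idx = {j: k for k, j in enumerate(skeleton.non_root_joints)}
    ref = reference.lengths
    out = np.empty_like(rel)
    for joint in skeleton.topological_order():
        par = skeleton.parent[joint]
        if par == skeleton.root:
            par_orig = np.zeros((rel.shape[0], 3))
            par_new = par_orig
        else:
            par_orig = rel[:, idx[par], :]
            par_new = out[:, idx[par], :]
        vec = rel[:, idx[joint], :] - par_orig
        norm = np.linalg.norm(vec, axis=1)
        if np.any(norm == 0):
            raise ZeroLengthSegmentError(
                f"segment {par}->{joint} has zero length at frame "
                f"{int(np.argmax(norm == 0))}"
            )
        out[:, idx[joint], :] = par_new + vec * (ref[joint] / norm)[:, None]
    return out


def normalize_session(
    session: MocapSession,
    reference: ReferenceLengths,
    target_hz: float = DEFAULT_TARGET_HZ,
    skeleton: Skeleton | None = None,
) -> tuple[np.ndarray, float]:
    """Full normalization: resample, center on root, scale segments.

    Returns the ``(T', 22, 3)`` normalized relative frames and the new rate.
    """
    skeleton = skeleton or default_skeleton()
    down = resample(session, target_hz)
    rel = center_on_root(down.frames, skeleton)
    return scale_segments(rel, reference, skeleton), down.sample_rate_hz
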