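"""Synthetic motion-capture corpora with the structure the analysis assumes.

The generator emulates a seated interview recorded with an inertial capture
suit: low-amplitude postural sway on every joint, sparse gesture bursts
concentrated in the arms, and a condition effect in which liars simply move
more — both the sway scale and the gesture rate are multiplied by
``lie_movement_multiplier`` in the lie condition, leaving the resting pose
unchanged. Each interviewee is randomly assigned one condition and recorded
in two sessions (Game and Wallet), mirroring the paired design of the study
corpus (90 interviewees, two ~2.5-minute sessions each at 60 Hz).

Mechanics:

* sway — independent AR(1) processes (coefficient 0.99 at 60 Hz, Gaussian
  innovations of scale ``sway_sd``) on every coordinate of every joint,
  initialized from their stationary distribution;
* gestures — Poisson arrivals at ``gesture_rate_hz``; each event displaces
  one randomly chosen arm chain (shoulder to hand, with weights growing
  toward the hand) along a random direction under a raised-cosine envelope
  of ``gesture_duration_s``.

Everything is a pure function of the configuration and seed: identical
inputs give bit-identical corpora.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import lfilter

from .io import MocapSession, SESSION_KINDS, CONDITIONS
from .skeleton import Skeleton, default_skeleton

#: AR(1) coefficient of the postural-sway model at 60 Hz
SWAY_AR_COEFF = 0.99

#: displacement weights along the shoulder-elbow-wrist-hand chain
_CHAIN_WEIGHTS = np.array([0.25, 0.5, 0.75, 1.0])


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; defaults mirror the emulated study corpus.

    ``lie_movement_multiplier`` scales both the sway and the gesture rate in
    the lie condition (1.0 = no effect; the default 1.5 is a moderate
    "liars move more" effect).
    """

    n_interviewees: int = 90
    session_length_s: float = 150.0
    sample_rate_hz: float = 60.0
    sway_sd: float = 0.002
    gesture_rate_hz: float = 0.05
    gesture_amplitude_m: float = 0.08
    gesture_duration_s: float = 1.0
    lie_movement_multiplier: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_interviewees < 2:
            raise ValueError("n_interviewees must be >= 2 (LOOCV needs >= 2 folds)")
        for name in (
            "session_length_s",
            "sample_rate_hz",
            "sway_sd",
            "gesture_rate_hz",
            "gesture_amplitude_m",
            "gesture_duration_s",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.lie_movement_multiplier < 0:
            raise ValueError("lie_movement_multiplier must be >= 0")


def template_pose(skeleton: Skeleton | None = None) -> np.ndarray:
    """A fixed, anatomically plausible seated pose, ``(23, 3)`` in meters.

    Coordinates are right-handed, y-up, z forward; the pose is exactly
    left-right mirror symmetric about the sagittal (x = 0) plane through the
    pelvis.
    """
    sk = skeleton or default_skeleton()
    half: dict[str, tuple[float, float, float]] = {
        "Pelvis": (0.0, 0.55, 0.0),
        "L5": (0.0, 0.65, 0.0),
        "L3": (0.0, 0.75, 0.0),
        "T12": (0.0, 0.85, 0.0),
        "T8": (0.0, 0.95, 0.0),
        "Neck": (0.0, 1.10, 0.0),
        "Head": (0.0, 1.22, 0.02),
        "LeftShoulder": (-0.20, 1.05, 0.0),
        "LeftElbow": (-0.25, 0.80, 0.03),
        "LeftWrist": (-0.26, 0.62, 0.20),
        "LeftHand": (-0.24, 0.58, 0.35),
        "LeftHip": (-0.10, 0.52, 0.0),
        "LeftKnee": (-0.13, 0.50, 0.45),
        "LeftAnkle": (-0.13, 0.08, 0.42),
        "LeftToe": (-0.13, 0.02, 0.60),
    }
    pose = np.empty((23, 3))
    for joint, (x, y, z) in half.items():
        pose[sk.index[joint]] = (x, y, z)
    for left, right in sk.mirror_pair.items():
        x, y, z = half[left]
        pose[sk.index[right]] = (-x, y, z)
    return pose


def _sway(
    rng: np.random.Generator, n_frames: int, sd: float
) -> np.ndarray:
    """Stationary AR(1) sway, ``(T, 23, 3)``."""
    phi = SWAY_AR_COEFF
    stationary_sd = sd / np.sqrt(1.0 - phi**2)
    x0 = rng.normal(0.0, stationary_sd, size=(23, 3))
    innovations = rng.normal(0.0, sd, size=(n_frames, 23, 3))
    driven = lfilter([1.0], [1.0, -phi], innovations, axis=0)
    decay = phi ** np.arange(1, n_frames + 1)
    return driven + decay[:, None, None] * x0[None, :, :]


def _add_gestures(
    frames: np.ndarray,
    rng: np.random.Generator,
    config: SyntheticConfig,
    rate_hz: float,
    skeleton: Skeleton,
) -> None:
    """Superimpose Poisson-arriving raised-cosine arm displacements in place."""
    duration = config.session_length_s
    n_events = rng.poisson(rate_hz * duration)
    times = np.sort(rng.uniform(0.0, duration, size=n_events))
    t = np.arange(frames.shape[0]) / config.sample_rate_hz
    chains = {
        "left": ["LeftShoulder", "LeftElbow", "LeftWrist", "LeftHand"],
        "right": ["RightShoulder", "RightElbow", "RightWrist", "RightHand"],
    }
    for t0 in times:
        side = "left" if rng.random() < 0.5 else "right"
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        mask = (t >= t0) & (t < t0 + config.gesture_duration_s)
        if not mask.any():
            continue
        phase = (t[mask] - t0) / config.gesture_duration_s
        envelope = 0.5 * config.gesture_amplitude_m * (1.0 - np.cos(2.0 * np.pi * phase))
        for joint, w in zip(chains[side], _CHAIN_WEIGHTS):
            frames[mask, skeleton.index[joint], :] += (
                w * envelope[:, None] * direction[None, :]
            )


def generate_session(
    config: SyntheticConfig,
    condition: str,
    session_kind: str,
    interviewee_id: str | int,
    seed: int,
    skeleton: Skeleton | None = None,
) -> MocapSession:
    """Generate one labeled session; fully determined by ``seed``."""
    if condition not in CONDITIONS:
        raise ValueError(f"condition must be one of {CONDITIONS}, got {condition!r}")
    if session_kind not in SESSION_KINDS:
        raise ValueError(
            f"session_kind must be one of {SESSION_KINDS}, got {session_kind!r}"
        )
    sk = skeleton or default_skeleton()
    rng = np.random.default_rng(seed)
    n_frames = int(round(config.session_length_s * config.sample_rate_hz))
    mult = config.lie_movement_multiplier if condition == "lie" else 1.0
    frames = template_pose(sk)[None, :, :] + _sway(rng, n_frames, config.sway_sd * mult)
    _add_gestures(frames, rng, config, config.gesture_rate_hz * mult, sk)
    return MocapSession(
        frames=frames,
        sample_rate_hz=config.sample_rate_hz,
        interviewee_id=str(interviewee_id),
        session_kind=session_kind,
        condition=condition,
        skeleton=sk,
    )


def generate_corpus(
    config: SyntheticConfig, skeleton: Skeleton | None = None
) -> list[MocapSession]:
    """Generate a balanced paired corpus: 2 sessions per interviewee.

    Half of the interviewees (randomly assigned via a seeded permutation)
    are liars in both of their sessions; ``n_interviewees`` must be even.
    """
    if config.n_interviewees % 2 != 0:
        raise ValueError(
            "n_interviewees must be even so that truth and lie conditions "
            f"can be balanced, got {config.n_interviewees}"
        )
    sk = skeleton or default_skeleton()
    rng = np.random.default_rng(config.seed)
    half = config.n_interviewees // 2
    conditions = np.array(["truth"] * half + ["lie"] * half)
    conditions = conditions[rng.permutation(config.n_interviewees)]
    session_seeds = rng.integers(0, 2**31 - 1, size=2 * config.n_interviewees)
    corpus: list[MocapSession] = []
    for i in range(config.n_interviewees):
        for k, kind in enumerate(SESSION_KINDS):
            corpus.append(
                generate_session(
                    config,
                    condition=str(conditions[i]),
                    session_kind=kind,
                    interviewee_id=f"p{i:03d}",
                    seed=int(session_seeds[2 * i + k]),
                    skeleton=sk,
                )
            )
    return corpus
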