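"""Reading and writing labeled motion-capture sessions and corpus manifests.

Native session dialect: a long-header CSV with one row per frame and columns
``<JointName>_x, <JointName>_y, <JointName>_z`` for the 23 canonical joints,
in canonical joint order, units meters. Corpora are described by a sidecar
manifest CSV with header ``path,interviewee_id,session_kind,condition``;
session paths are resolved relative to the manifest's directory.

Files produced by other capture pipelines are mapped onto the canonical
skeleton through a *dialect*: a mapping from canonical joint name to the
three column names holding its x/y/z coordinates (loadable from YAML via
:func:`load_dialect`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ColumnCountError,
    DuplicateSessionError,
    NonNumericError,
    UnknownConditionError,
    UnmappedJointError,
)
from .skeleton import Skeleton, default_skeleton

logger = logging.getLogger(__name__)

SESSION_KINDS = ("game", "wallet")
CONDITIONS = ("truth", "lie")

#: condition token for prediction-only sessions
UNKNOWN = "unknown"


@dataclass
class MocapSession:
    """One recorded interview: joint trajectories plus labels.

    Attributes
    ----------
    frames
        ``(T, 23, 3)`` float array of joint positions in meters, joint axis
        in canonical skeleton order.
    sample_rate_hz
        Sampling rate of the recording.
    interviewee_id
        Opaque identifier of the interviewee; the unit of cross-validation.
    session_kind
        ``"game"`` (reverse-order questions) or ``"wallet"``.
    condition
        ``"truth"``, ``"lie"``, or ``"unknown"`` for prediction-only use.
    """

    frames: np.ndarray
    sample_rate_hz: float
    interviewee_id: str
    session_kind: str
    condition: str = UNKNOWN
    skeleton: Skeleton = field(default_factory=default_skeleton, repr=False)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[1:] != (23, 3):
            raise ValueError(
                f"frames must have shape (T, 23, 3), got {self.frames.shape}"
            )
        if self.frames.shape[0] < 2:
            raise ValueError("a session needs at least 2 frames")
        if not np.isfinite(self.frames).all():
            raise ValueError("frames contain non-finite coordinates")
        if self.sample_rate_hz <= 0:
            raise ValueError("sample_rate_hz must be positive")
        if self.session_kind not in SESSION_KINDS:
            raise ValueError(
                f"session_kind must be one of {SESSION_KINDS}, got {self.session_kind!r}"
            )
        if self.condition not in CONDITIONS + (UNKNOWN,):
            raise ValueError(
                f"condition must be truth/lie/unknown, got {self.condition!r}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.sample_rate_hz

    def with_frames(self, frames: np.ndarray, sample_rate_hz: float | None = None) -> "MocapSession":
        return replace(
            self,
            frames=frames,
            sample_rate_hz=self.sample_rate_hz if sample_rate_hz is None else sample_rate_hz,
        )


def native_dialect(skeleton: Skeleton | None = None) -> dict[str, tuple[str, str, str]]:
    """Column mapping of the native dialect: ``Joint -> (Joint_x, Joint_y, Joint_z)``."""
    skeleton = skeleton or default_skeleton()
    return {j: (f"{j}_x", f"{j}_y", f"{j}_z") for j in skeleton.joints}


def load_dialect(path: str | Path) -> dict[str, tuple[str, str, str]]:
    """Load an adapter dialect from YAML: ``canonical joint -> [col_x, col_y, col_z]``."""
    raw = yaml.safe_load(Path(path).read_text())
    out: dict[str, tuple[str, str, str]] = {}
    for joint, cols in raw.items():
        if len(cols) != 3:
            raise ValueError(f"dialect entry for {joint!r} must list 3 columns")
        out[str(joint)] = tuple(str(c) for c in cols)  # type: ignore[assignment]
    return out


def read_session(
    path: str | Path,
    *,
    sample_rate_hz: float = 60.0,
    dialect: dict[str, tuple[str, str, str]] | None = None,
    interviewee_id: str = "",
    session_kind: str = "game",
    condition: str = UNKNOWN,
    skeleton: Skeleton | None = None,
) -> MocapSession:
    """Read one session CSV and map its columns onto the canonical skeleton.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ColumnCountError
        If the file does not have one column per expected coordinate.
    NonNumericError
        If any coordinate cell fails to parse as a number.
    UnmappedJointError
        If a canonical joint's columns are missing from the header.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    skeleton = skeleton or default_skeleton()
    dialect = dialect or native_dialect(skeleton)

    table = pd.read_csv(path, header=0, float_precision="round_trip")
    missing = [
        j for j in skeleton.joints
        if j not in dialect
        or any(c not in table.columns for c in dialect[j])
    ]
    if missing:
        raise UnmappedJointError(
            f"{path}: no columns for canonical joint(s) {', '.join(missing)}"
        )
    expected_cols = 3 * len(skeleton.joints)
    if table.shape[1] != expected_cols:
        raise ColumnCountError(
            f"{path}: expected {expected_cols} columns, found {table.shape[1]}"
        )

    frames = np.empty((table.shape[0], 23, 3), dtype=float)
    for k, joint in enumerate(skeleton.joints):
        cols = list(dialect[joint])
        block = table[cols].apply(pd.to_numeric, errors="coerce").to_numpy()
        if np.isnan(block).any():
            bad = table[cols].iloc[np.argwhere(np.isnan(block))[0][0]]
            raise NonNumericError(
                f"{path}: non-numeric value in columns {cols} (row values {bad.tolist()})"
            )
        frames[:, k, :] = block
    return MocapSession(
        frames=frames,
        sample_rate_hz=sample_rate_hz,
        interviewee_id=str(interviewee_id),
        session_kind=session_kind,
        condition=condition,
        skeleton=skeleton,
    )


def write_session(session: MocapSession, path: str | Path) -> None:
    """Write a session in the native CSV dialect (full float precision)."""
    path = Path(path)
    cols: list[str] = []
    for j in session.skeleton.joints:
        cols += [f"{j}_x", f"{j}_y", f"{j}_z"]
    flat = session.frames.reshape(session.n_frames, -1)
    pd.DataFrame(flat, columns=cols).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_manifest(
    path: str | Path,
    *,
    sample_rate_hz: float = 60.0,
    dialect: dict[str, tuple[str, str, str]] | None = None,
    skeleton: Skeleton | None = None,
) -> list[MocapSession]:
    """Load every session listed in a manifest CSV.

    The manifest has header ``path,interviewee_id,session_kind,condition``.
    Each interviewee may have at most one session per kind.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    table = pd.read_csv(path, dtype=str)
    required = ["path", "interviewee_id", "session_kind", "condition"]
    if list(table.columns) != required:
        raise ValueError(
            f"{path}: manifest header must be {','.join(required)}"
        )
    if table.empty:
        logger.warning("manifest %s lists no sessions", path)
        return []

    seen: set[tuple[str, str]] = set()
    corpus: list[MocapSession] = []
    for row in table.itertuples(index=False):
        key = (row.interviewee_id, row.session_kind)
        if key in seen:
            raise DuplicateSessionError(
                f"{path}: duplicate session for interviewee "
                f"{row.interviewee_id!r}, kind {row.session_kind!r}"
            )
        seen.add(key)
        if row.condition not in CONDITIONS + (UNKNOWN,):
            raise UnknownConditionError(
                f"{path}: unknown condition token {row.condition!r} "
                f"for interviewee {row.interviewee_id!r}"
            )
        session_path = Path(row.path)
        if not session_path.is_absolute():
            session_path = path.parent / session_path
        corpus.append(
            read_session(
                session_path,
                sample_rate_hz=sample_rate_hz,
                dialect=dialect,
                interviewee_id=row.interviewee_id,
                session_kind=row.session_kind,
                condition=row.condition,
                skeleton=skeleton,
            )
        )
    return corpus


def write_manifest(
    corpus: list[MocapSession], directory: str | Path, name: str = "manifest.csv"
) -> Path:
    """Write each session as CSV plus a manifest; returns the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows = []
    for s in corpus:
        fname = f"{s.interviewee_id}_{s.session_kind}.csv"
        write_session(s, directory / fname)
        rows.append(
            {
                "path": fname,
                "interviewee_id": s.interviewee_id,
                "session_kind": s.session_kind,
                "condition": s.condition,
            }
        )
    manifest = directory / name
    pd.DataFrame(rows, columns=["path", "interviewee_id", "session_kind", "condition"]).to_csv(
        manifest, index=False
    )
    return manifest
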