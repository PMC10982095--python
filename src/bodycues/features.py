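"""The 67 per-frame geometric features and their catalogue.

Four feature types, computed on normalized (root-relative, segment-scaled,
downsampled) frames:

movement (30)
    Euclidean displacement of each of the 22 joints between consecutive
    frames, plus totals for the six body parts, the upper body (arms, torso,
    head) and the full body. Streams have length T-1.
joint_angle (10)
    For nine joints (neck, shoulders, elbows, hips, knees), the angle in
    degrees between the incoming segment vector (parent -> joint) and the
    outgoing one (joint -> child); a fully extended chain gives 0 degrees.
    Plus the mean of the nine.
joint_distance (12)
    Eleven named inter-joint distances (the pelvis being the origin of the
    centered frame) plus their mean.
symmetry (15)
    Each pose is mirrored in the plane through the root perpendicular to the
    hip axis (normal: unit vector from left hip to right hip). Eight streams
    compare the mirrored left joints with their right counterparts; six
    compare each midline joint with its own mirror image; the fifteenth is
    the mean of the fourteen.

The catalogue records, per feature, its type, the joints involved, the body
parts touched, and an extent class used in the body-part breakdowns:
``single`` (one body part), ``two`` (exactly two), ``all`` (three or more,
i.e. the upper/full-body aggregates and the averages over all joints).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .skeleton import BODY_PARTS, Skeleton, default_skeleton

FEATURE_TYPES = ("movement", "joint_angle", "joint_distance", "symmetry")

#: expected catalogue counts per type
TYPE_COUNTS = {"movement": 30, "joint_angle": 10, "joint_distance": 12, "symmetry": 15}
N_FEATURES = 67


@dataclass(frozen=True)
class FeatureDescriptor:
    feature_id: str
    feature_type: str
    joints_involved: tuple[str, ...]
    body_parts_involved: tuple[str, ...]
    n_body_parts_class: str  # single | two | all

    def __post_init__(self) -> None:
        assert self.feature_type in FEATURE_TYPES
        assert len(self.body_parts_involved) >= 1


# angle joints: (name, joint, parent override, child)
_ANGLE_SPECS = [
    ("neck_angle", "Neck", None, "Head"),
    ("left_shoulder_angle", "LeftShoulder", None, "LeftElbow"),
    ("right_shoulder_angle", "RightShoulder", None, "RightElbow"),
    ("left_elbow_angle", "LeftElbow", None, "LeftWrist"),
    ("right_elbow_angle", "RightElbow", None, "RightWrist"),
    ("left_hip_angle", "LeftHip", None, "LeftKnee"),
    ("right_hip_angle", "RightHip", None, "RightKnee"),
    ("left_knee_angle", "LeftKnee", None, "LeftAnkle"),
    ("right_knee_angle", "RightKnee", None, "RightAnkle"),
]

# distance pairs; "Pelvis" denotes the origin of the centered frame
_DISTANCE_SPECS = [
    ("head_left_elbow_distance", "Head", "LeftElbow"),
    ("head_right_elbow_distance", "Head", "RightElbow"),
    ("left_hand_right_hand_distance", "LeftHand", "RightHand"),
    ("left_hand_right_elbow_distance", "LeftHand", "RightElbow"),
    ("right_hand_left_elbow_distance", "RightHand", "LeftElbow"),
    ("left_hand_left_knee_distance", "LeftHand", "LeftKnee"),
    ("right_hand_right_knee_distance", "RightHand", "RightKnee"),
    ("left_knee_right_knee_distance", "LeftKnee", "RightKnee"),
    ("left_ankle_right_ankle_distance", "LeftAnkle", "RightAnkle"),
    ("pelvis_left_ankle_distance", "Pelvis", "LeftAnkle"),
    ("pelvis_right_ankle_distance", "Pelvis", "RightAnkle"),
]

_PART_ORDER = ("left_arm", "right_arm", "left_leg", "right_leg", "torso", "head")


def _extent_class(parts: tuple[str, ...]) -> str:
    if len(parts) == 1:
        return "single"
    if len(parts) == 2:
        return "two"
    return "all"


def _snake(joint: str) -> str:
    out = []
    for i, ch in enumerate(joint):
        if ch.isupper() and i > 0:
            out.append("_")
        out.append(ch.lower())
    return "".join(out)


def build_catalogue(skeleton: Skeleton | None = None) -> tuple[FeatureDescriptor, ...]:
    """Construct the 67-descriptor catalogue in canonical feature order."""
    sk = skeleton or default_skeleton()
    descs: list[FeatureDescriptor] = []

    # movement: 22 per-joint, 6 part totals, upper body, full body
    for j in sk.non_root_joints:
        part = sk.body_part[j]
        descs.append(
            FeatureDescriptor(f"{_snake(j)}_movement", "movement", (j,), (part,), "single")
        )
    for part in _PART_ORDER:
        descs.append(
            FeatureDescriptor(
                f"{part}_total_movement",
                "movement",
                sk.joints_of_part(part),
                (part,),
                "single",
            )
        )
    upper_parts = ("left_arm", "right_arm", "torso", "head")
    upper_joints = tuple(j for p in upper_parts for j in sk.joints_of_part(p))
    descs.append(
        FeatureDescriptor("upper_body_movement", "movement", upper_joints, upper_parts, "all")
    )
    descs.append(
        FeatureDescriptor(
            "full_body_movement", "movement", sk.non_root_joints, tuple(_PART_ORDER), "all"
        )
    )

    # joint angles: attributed to the body part of the pivot joint
    for name, joint, _, child in _ANGLE_SPECS:
        parent = sk.parent[joint]
        part = sk.body_part[joint]
        descs.append(
            FeatureDescriptor(name, "joint_angle", (parent, joint, child), (part,), "single")
        )
    angle_joints = tuple(
        dict.fromkeys(
            j for _, pivot, _, child in _ANGLE_SPECS
            for j in (sk.parent[pivot], pivot, child)
        )
    )
    descs.append(
        FeatureDescriptor(
            "mean_joint_angle", "joint_angle", angle_joints, tuple(_PART_ORDER), "all"
        )
    )

    # joint distances: union of the two endpoints' parts (pelvis adds none)
    for name, a, b in _DISTANCE_SPECS:
        joints = tuple(j for j in (a, b) if j != sk.root)
        parts = tuple(dict.fromkeys(sk.body_part[j] for j in joints))
        descs.append(
            FeatureDescriptor(name, "joint_distance", (a, b), parts, _extent_class(parts))
        )
    descs.append(
        FeatureDescriptor(
            "mean_joint_distance",
            "joint_distance",
            tuple(dict.fromkeys(j for _, a, b in _DISTANCE_SPECS for j in (a, b))),
            tuple(_PART_ORDER),
            "all",
        )
    )

    # symmetry: paired left joints vs right counterparts, then midline joints
    for left in [j for j in sk.joints if j in sk.mirror_pair]:
        right = sk.mirror_pair[left]
        parts = (sk.body_part[left], sk.body_part[right])
        descs.append(
            FeatureDescriptor(
                f"{_snake(left)}_symmetry", "symmetry", (left, right), parts, "two"
            )
        )
    for j in sk.midline_joints:
        descs.append(
            FeatureDescriptor(
                f"{_snake(j)}_symmetry", "symmetry", (j,), (sk.body_part[j],), "single"
            )
        )
    descs.append(
        FeatureDescriptor(
            "full_body_symmetry", "symmetry", sk.non_root_joints, tuple(_PART_ORDER), "all"
        )
    )

    counts = {t: sum(1 for d in descs if d.feature_type == t) for t in FEATURE_TYPES}
    assert counts == TYPE_COUNTS, f"catalogue counts {counts} != {TYPE_COUNTS}"
    assert len(descs) == N_FEATURES
    ids = [d.feature_id for d in descs]
    assert len(set(ids)) == N_FEATURES, "duplicate feature ids"
    return tuple(descs)


class FeatureCatalogue:
    """Ordered catalogue of the 67 feature descriptors."""

    def __init__(self, skeleton: Skeleton | None = None) -> None:
        self.skeleton = skeleton or default_skeleton()
        self.descriptors = build_catalogue(self.skeleton)
        self.index = {d.feature_id: i for i, d in enumerate(self.descriptors)}

    def __len__(self) -> int:
        return len(self.descriptors)

    def __iter__(self):
        return iter(self.descriptors)

    def __getitem__(self, key: int | str) -> FeatureDescriptor:
        if isinstance(key, str):
            return self.descriptors[self.index[key]]
        return self.descriptors[key]

    def ids(self) -> tuple[str, ...]:
        return tuple(d.feature_id for d in self.descriptors)

    def of_type(self, feature_type: str) -> tuple[int, ...]:
        return tuple(
            i for i, d in enumerate(self.descriptors) if d.feature_type == feature_type
        )

    def of_body_part(self, part: str) -> tuple[int, ...]:
        """Indices of features linked to ``part`` (membership, not exclusivity)."""
        assert part in BODY_PARTS
        return tuple(
            i for i, d in enumerate(self.descriptors) if part in d.body_parts_involved
        )

    def of_extent(self, extent: str) -> tuple[int, ...]:
        return tuple(
            i for i, d in enumerate(self.descriptors) if d.n_body_parts_class == extent
        )

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "feature_id": [d.feature_id for d in self.descriptors],
                "feature_type": [d.feature_type for d in self.descriptors],
                "joints_involved": ["|".join(d.joints_involved) for d in self.descriptors],
                "body_parts_involved": [
                    "|".join(d.body_parts_involved) for d in self.descriptors
                ],
                "n_body_parts_class": [d.n_body_parts_class for d in self.descriptors],
            }
        )


@dataclass
class FeatureStreams:
    """Per-frame feature values for one session.

    ``pose`` holds the 37 pose features (angles, distances, symmetry) over T
    frames; ``movement`` holds the 30 movement features over the T-1 frame
    transitions. Columns follow catalogue order within each block.
    """

    movement: np.ndarray  # (T-1, 30)
    pose: np.ndarray  # (T, 37)
    sample_rate_hz: float
    catalogue: FeatureCatalogue

    @property
    def n_frames(self) -> int:
        return self.pose.shape[0]

    def values(self, feature_index: int) -> np.ndarray:
        """Stream of one catalogue feature (length T-1 for movement, else T)."""
        if feature_index < 30:
            return self.movement[:, feature_index]
        return self.pose[:, feature_index - 30]


def _joint_rows(skeleton: Skeleton) -> dict[str, int]:
    return {j: k for k, j in enumerate(skeleton.non_root_joints)}


def movement_features(
    relative_frames: np.ndarray, skeleton: Skeleton | None = None
) -> np.ndarray:
    """30 movement streams of length T-1 (per-joint plus aggregate totals)."""
    sk = skeleton or default_skeleton()
    rel = np.asarray(relative_frames, dtype=float)
    if rel.shape[0] < 2:
        raise ValueError("movement features need at least 2 frames")
    rows = _joint_rows(sk)
    disp = np.linalg.norm(np.diff(rel, axis=0), axis=2)  # (T-1, 22)
    out = np.empty((disp.shape[0], 30))
    out[:, :22] = disp
    for k, part in enumerate(_PART_ORDER):
        cols = [rows[j] for j in sk.joints_of_part(part)]
        out[:, 22 + k] = disp[:, cols].sum(axis=1)
    upper = [rows[j] for p in ("left_arm", "right_arm", "torso", "head") for j in sk.joints_of_part(p)]
    out[:, 28] = disp[:, upper].sum(axis=1)
    out[:, 29] = disp.sum(axis=1)
    return out


def _positions(rel: np.ndarray, rows: dict[str, int], joint: str, root: str) -> np.ndarray:
    if joint == root:
        return np.zeros((rel.shape[0], 3))
    return rel[:, rows[joint], :]


def joint_angle_features(
    relative_frames: np.ndarray, skeleton: Skeleton | None = None
) -> np.ndarray:
    """10 angle streams (degrees) of length T; extended chain = 0 degrees."""
    sk = skeleton or default_skeleton()
    rel = np.asarray(relative_frames, dtype=float)
    rows = _joint_rows(sk)
    out = np.empty((rel.shape[0], 10))
    for k, (_, joint, _, child) in enumerate(_ANGLE_SPECS):
        parent = sk.parent[joint]
        p = _positions(rel, rows, parent, sk.root)
        j = rel[:, rows[joint], :]
        c = rel[:, rows[child], :]
        v1 = j - p
        v2 = c - j
        n1 = np.linalg.norm(v1, axis=1)
        n2 = np.linalg.norm(v2, axis=1)
        if np.any(n1 == 0) or np.any(n2 == 0):
            raise ValueError(f"zero-length segment at angle joint {joint}")
        cosang = np.clip((v1 * v2).sum(axis=1) / (n1 * n2), -1.0, 1.0)
        out[:, k] = np.degrees(np.arccos(cosang))
    out[:, 9] = out[:, :9].mean(axis=1)
    return out


def joint_distance_features(
    relative_frames: np.ndarray, skeleton: Skeleton | None = None
) -> np.ndarray:
    """12 distance streams of length T (11 named pairs plus their mean)."""
    sk = skeleton or default_skeleton()
    rel = np.asarray(relative_frames, dtype=float)
    rows = _joint_rows(sk)
    out = np.empty((rel.shape[0], 12))
    for k, (_, a, b) in enumerate(_DISTANCE_SPECS):
        pa = _positions(rel, rows, a, sk.root)
        pb = _positions(rel, rows, b, sk.root)
        out[:, k] = np.linalg.norm(pa - pb, axis=1)
    out[:, 11] = out[:, :11].mean(axis=1)
    return out


def mirror_matrix(normal: np.ndarray) -> np.ndarray:
    """Householder reflection through the plane at the origin with unit ``normal``."""
    n = np.asarray(normal, dtype=float)
    n = n / np.linalg.norm(n)
    return np.eye(3) - 2.0 * np.outer(n, n)


def symmetry_features(
    relative_frames: np.ndarray, skeleton: Skeleton | None = None
) -> np.ndarray:
    """15 symmetry streams of length T.

    The mirror plane passes through the root with normal along the unit
    vector from the left hip to the right hip (recomputed per frame).
    """
    sk = skeleton or default_skeleton()
    rel = np.asarray(relative_frames, dtype=float)
    rows = _joint_rows(sk)
    lhip = rel[:, rows["LeftHip"], :]
    rhip = rel[:, rows["RightHip"], :]
    axis = rhip - lhip
    norm = np.linalg.norm(axis, axis=1)
    if np.any(norm == 0):
        raise ValueError("degenerate hip axis: left and right hip coincide")
    n = axis / norm[:, None]
    # reflect p across the plane: p - 2 (p . n) n, per frame
    proj = np.einsum("tjc,tc->tj", rel, n)  # (T, 22) dot products
    mirrored = rel - 2.0 * proj[..., None] * n[:, None, :]

    out = np.empty((rel.shape[0], 15))
    lefts = [j for j in sk.joints if j in sk.mirror_pair]
    for k, left in enumerate(lefts):
        right = sk.mirror_pair[left]
        out[:, k] = np.linalg.norm(
            mirrored[:, rows[left], :] - rel[:, rows[right], :], axis=1
        )
    for k, j in enumerate(sk.midline_joints):
        out[:, 8 + k] = np.linalg.norm(
            mirrored[:, rows[j], :] - rel[:, rows[j], :], axis=1
        )
    out[:, 14] = out[:, :14].mean(axis=1)
    return out


def extract_all(
    relative_frames: np.ndarray,
    sample_rate_hz: float,
    skeleton: Skeleton | None = None,
    catalogue: FeatureCatalogue | None = None,
) -> FeatureStreams:
    """Compute all 67 streams for one normalized session."""
    sk = skeleton or default_skeleton()
    cat = catalogue or FeatureCatalogue(sk)
    movement = movement_features(relative_frames, sk)
    pose = np.hstack(
        [
            joint_angle_features(relative_frames, sk),
            joint_distance_features(relative_frames, sk),
            symmetry_features(relative_frames, sk),
        ]
    )
    return FeatureStreams(
        movement=movement, pose=pose, sample_rate_hz=sample_rate_hz, catalogue=cat
    )
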