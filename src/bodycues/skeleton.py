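"""Canonical 23-joint skeleton: names, tree, body parts, left/right pairing.

The skeleton follows the 23-segment layout of inertial motion-capture suits:
an axial chain Pelvis-L5-L3-T12-T8-Neck-Head, arms parented at T8
(Shoulder-Elbow-Wrist-Hand per side) and legs parented at the pelvis
(Hip-Knee-Ankle-Toe per side). The pelvis is the root of the kinematic tree
and the origin of the body-relative coordinate system used downstream.

Joint order is canonical: every array with a joint axis in this package uses
the order of :attr:`Skeleton.joints`.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import SkeletonError

BODY_PARTS = ("left_arm", "right_arm", "left_leg", "right_leg", "torso", "head")

#: body-part cardinalities over the 22 non-root joints
_PART_SIZES = {
    "left_arm": 4,
    "right_arm": 4,
    "left_leg": 4,
    "right_leg": 4,
    "torso": 4,
    "head": 2,
}


@dataclass(frozen=True)
class Skeleton:
    """A rooted kinematic tree of 23 named joints.

    Parameters
    ----------
    joints
        The 23 joint names in canonical order.
    root
        Name of the root joint (the pelvis).
    parent
        Parent of each of the 22 non-root joints; forms a tree rooted at
        ``root``.
    body_part
        Body part (one of ``BODY_PARTS``) of each non-root joint.
    mirror_pair
        Map of the 8 left joints to their right counterparts.
    """

    joints: tuple[str, ...]
    root: str
    parent: dict[str, str]
    body_part: dict[str, str]
    mirror_pair: dict[str, str]
    index: dict[str, int] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "index", {name: i for i, name in enumerate(self.joints)}
        )
        self._validate()

    # -- derived views -----------------------------------------------------

    @property
    def non_root_joints(self) -> tuple[str, ...]:
        """The 22 joints other than the root, in canonical order."""
        return tuple(j for j in self.joints if j != self.root)

    @property
    def midline_joints(self) -> tuple[str, ...]:
        """The 6 unpaired non-root joints (axial chain above the pelvis)."""
        paired = set(self.mirror_pair) | set(self.mirror_pair.values())
        return tuple(
            j for j in self.joints if j != self.root and j not in paired
        )

    @property
    def segments(self) -> tuple[tuple[str, str], ...]:
        """The 22 (parent, child) segments in canonical child order."""
        return tuple((self.parent[j], j) for j in self.non_root_joints)

    def joints_of_part(self, part: str) -> tuple[str, ...]:
        return tuple(j for j in self.non_root_joints if self.body_part[j] == part)

    def topological_order(self) -> tuple[str, ...]:
        """Non-root joints ordered so every parent precedes its children."""
        order: list[str] = []
        placed = {self.root}
        pending = list(self.non_root_joints)
        while pending:
            progressed = False
            for j in list(pending):
                if self.parent[j] in placed:
                    order.append(j)
                    placed.add(j)
                    pending.remove(j)
                    progressed = True
            if not progressed:  # pragma: no cover - guarded by _validate
                raise SkeletonError(f"parent map is not a tree: stuck at {pending}")
        return tuple(order)

    # -- validation --------------------------------------------------------

    def _validate(self) -> None:
        if len(self.joints) != 23 or len(set(self.joints)) != 23:
            raise SkeletonError("skeleton must have 23 uniquely named joints")
        if self.root not in self.joints:
            raise SkeletonError(f"root joint {self.root!r} not in joint list")
        if self.root in self.parent:
            raise SkeletonError("root joint must not have a parent")
        non_root = set(self.joints) - {self.root}
        if set(self.parent) != non_root:
            raise SkeletonError("parent map must cover exactly the 22 non-root joints")
        for child, par in self.parent.items():
            if par not in self.joints:
                raise SkeletonError(f"unknown parent {par!r} of {child!r}")
        # tree check: walking up from every joint must reach the root
        for j in non_root:
            seen = set()
            cur = j
            while cur != self.root:
                if cur in seen:
                    raise SkeletonError(f"cycle in parent map at {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]
        if set(self.body_part) != non_root:
            raise SkeletonError("body_part must cover exactly the 22 non-root joints")
        for part, size in _PART_SIZES.items():
            n = sum(1 for p in self.body_part.values() if p == part)
            if n != size:
                raise SkeletonError(f"body part {part!r} has {n} joints, expected {size}")
        lefts = set(self.mirror_pair)
        rights = set(self.mirror_pair.values())
        if len(lefts) != 8 or len(rights) != 8 or lefts & rights:
            raise SkeletonError("mirror_pair must map 8 distinct left joints to 8 right joints")
        if not (lefts | rights) <= non_root:
            raise SkeletonError("mirror pairs must be non-root joints")
        if len(self.midline_joints) != 6:
            raise SkeletonError("expected 6 unpaired midline joints")


def load_skeleton(path: str | Path | None = None) -> Skeleton:
    """Load a skeleton definition from YAML (the packaged default if no path)."""
    if path is None:
        ref = importlib.resources.files("bodycues").joinpath("data/skeleton.yaml")
        text = ref.read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    return Skeleton(
        joints=tuple(raw["joints"]),
        root=raw["root"],
        parent=dict(raw["parent"]),
        body_part=dict(raw["body_part"]),
        mirror_pair=dict(raw["mirror_pair"]),
    )


_DEFAULT: Skeleton | None = None


def default_skeleton() -> Skeleton:
    """The packaged canonical skeleton (cached)."""
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = load_skeleton()
    return _DEFAULT
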