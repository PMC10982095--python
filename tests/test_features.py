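import numpy as np
import pytest

import bodycues as bc
from bodycues.features import (
    FeatureCatalogue,
    joint_angle_features,
    joint_distance_features,
    mirror_matrix,
    movement_features,
    symmetry_features,
)
from bodycues.normalize import center_on_root
from conftest import random_rotation


@pytest.fixture(scope="module")
def catalogue():
    return FeatureCatalogue()


@pytest.fixture()
def rel_template():
    return center_on_root(bc.template_pose()[None, :, :])


def _rows(skeleton):
    return {j: k for k, j in enumerate(skeleton.non_root_joints)}


class TestCatalogue:
    def test_counts_by_type(self, catalogue):
        counts = {
            t: len(catalogue.of_type(t))
            for t in ("movement", "joint_angle", "joint_distance", "symmetry")
        }
        assert counts == {
            "movement": 30, "joint_angle": 10, "joint_distance": 12, "symmetry": 15,
        }
        assert len(catalogue) == 67

    def test_every_feature_maps_to_a_body_part(self, catalogue):
        assert all(len(d.body_parts_involved) >= 1 for d in catalogue)

    def test_extent_classes_partition_catalogue(self, catalogue):
        sizes = {e: len(catalogue.of_extent(e)) for e in ("single", "two", "all")}
        assert sum(sizes.values()) == 67
        joint_sets = [set(catalogue.of_extent(e)) for e in ("single", "two", "all")]
        assert not (joint_sets[0] & joint_sets[1])
        assert not (joint_sets[0] & joint_sets[2])
        assert not (joint_sets[1] & joint_sets[2])

    def test_body_part_union_covers_all_features(self, catalogue):
        union = set()
        for part in ("left_arm", "right_arm", "left_leg", "right_leg", "torso", "head"):
            union |= set(catalogue.of_body_part(part))
        assert union == set(range(67))


class TestMovement:
    def test_static_session_all_zero(self, rel_template):
        rel = np.repeat(rel_template, 5, axis=0)
        assert np.allclose(movement_features(rel), 0.0)

    def test_single_joint_345_displacement(self, skeleton, rel_template):
        rel = np.repeat(rel_template, 2, axis=0)
        rows = _rows(skeleton)
        rel[1, rows["LeftHand"]] += (0.3, 0.4, 0.0)
        out = movement_features(rel)
        cat = FeatureCatalogue()
        assert out[0, cat.index["left_hand_movement"]] == pytest.approx(0.5)
        assert out[0, cat.index["left_arm_total_movement"]] == pytest.approx(0.5)
        assert out[0, cat.index["upper_body_movement"]] == pytest.approx(0.5)
        assert out[0, cat.index["full_body_movement"]] == pytest.approx(0.5)
        assert out[0, cat.index["right_arm_total_movement"]] == pytest.approx(0.0)

    def test_needs_two_frames(self, rel_template):
        with pytest.raises(ValueError):
            movement_features(rel_template)

    def test_totals_conserve_member_sums(self, skeleton, rng):
        rel = center_on_root(
            bc.template_pose()[None] + rng.normal(0, 0.01, size=(20, 23, 3))
        )
        out = movement_features(rel)
        cat = FeatureCatalogue()
        rows = _rows(skeleton)
        for part in ("left_arm", "right_arm", "left_leg", "right_leg", "torso", "head"):
            member_cols = [rows[j] for j in skeleton.joints_of_part(part)]
            expect = np.linalg.norm(np.diff(rel, axis=0), axis=2)[:, member_cols].sum(axis=1)
            assert out[:, cat.index[f"{part}_total_movement"]] == pytest.approx(expect)
        assert out[:, cat.index["full_body_movement"]] == pytest.approx(
            out[:, :22].sum(axis=1)
        )


class TestAngles:
    def _arm_pose(self, skeleton, elbow_dir):
        """Template with the left forearm pointed along ``elbow_dir``."""
        rel = center_on_root(bc.template_pose()[None]).copy()
        rows = _rows(skeleton)
        shoulder, elbow = rel[0, rows["LeftShoulder"]], rel[0, rows["LeftElbow"]]
        upper = elbow - shoulder
        wrist = elbow + 0.25 * elbow_dir / np.linalg.norm(elbow_dir)
        rel[0, rows["LeftWrist"]] = wrist
        rel[0, rows["LeftHand"]] = wrist + 0.6 * (wrist - elbow)
        return rel, upper

    def test_extended_arm_is_zero_degrees(self, skeleton):
        rel, upper = self._arm_pose(skeleton, elbow_dir=np.array([1.0, 1.0, 1.0]))
        rel, _ = self._arm_pose(skeleton, elbow_dir=upper)
        out = joint_angle_features(rel)
        cat = FeatureCatalogue()
        assert out[0, cat.index["left_elbow_angle"] - 30] == pytest.approx(0.0, abs=1e-7)

    def test_perpendicular_forearm_is_ninety_degrees(self, skeleton):
        rel, upper = self._arm_pose(skeleton, elbow_dir=np.array([1.0, 0.0, 0.0]))
        perp = np.cross(upper, [0.0, 0.0, 1.0])
        rel, _ = self._arm_pose(skeleton, elbow_dir=perp)
        out = joint_angle_features(rel)
        cat = FeatureCatalogue()
        assert out[0, cat.index["left_elbow_angle"] - 30] == pytest.approx(90.0, abs=1e-7)

    def test_mean_is_mean_of_nine(self, rel_template):
        out = joint_angle_features(np.repeat(rel_template, 3, axis=0))
        assert out[:, 9] == pytest.approx(out[:, :9].mean(axis=1))
        assert ((out >= 0) & (out <= 180)).all()


class TestDistances:
    def test_coincident_hands_zero(self, skeleton, rel_template):
        rel = rel_template.copy()
        rows = _rows(skeleton)
        rel[0, rows["RightHand"]] = rel[0, rows["LeftHand"]]
        out = joint_distance_features(rel)
        cat = FeatureCatalogue()
        assert out[0, cat.index["left_hand_right_hand_distance"] - 40] == pytest.approx(0.0)

    def test_hand_separation(self, skeleton, rel_template):
        rel = rel_template.copy()
        rows = _rows(skeleton)
        rel[0, rows["LeftHand"]] = (0.1, 0.0, 0.0)
        rel[0, rows["RightHand"]] = (-0.1, 0.0, 0.0)
        out = joint_distance_features(rel)
        cat = FeatureCatalogue()
        assert out[0, cat.index["left_hand_right_hand_distance"] - 40] == pytest.approx(0.2)

    def test_pelvis_distances_use_origin(self, skeleton, rel_template):
        rows = _rows(skeleton)
        out = joint_distance_features(rel_template)
        cat = FeatureCatalogue()
        expect = np.linalg.norm(rel_template[0, rows["LeftAnkle"]])
        assert out[0, cat.index["pelvis_left_ankle_distance"] - 40] == pytest.approx(expect)

    def test_mean_is_mean_of_eleven(self, rel_template):
        out = joint_distance_features(rel_template)
        assert out[0, 11] == pytest.approx(out[0, :11].mean())


class TestSymmetry:
    def test_symmetric_pose_all_zero(self, rel_template):
        assert np.allclose(symmetry_features(rel_template), 0.0, atol=1e-12)

    def test_displaced_hand_matches_reflection_oracle(self, skeleton, rel_template):
        rows = _rows(skeleton)
        rel = rel_template.copy()
        hip_axis = rel[0, rows["RightHip"]] - rel[0, rows["LeftHip"]]
        n = hip_axis / np.linalg.norm(hip_axis)
        rel[0, rows["LeftHand"]] += 0.1 * n
        out = symmetry_features(rel)
        cat = FeatureCatalogue()
        assert out[0, cat.index["left_hand_symmetry"] - 52] == pytest.approx(0.1, abs=1e-9)
        # explicit reflection-matrix oracle for every paired stream
        M = mirror_matrix(n)
        lefts = [j for j in skeleton.joints if j in skeleton.mirror_pair]
        for k, left in enumerate(lefts):
            right = skeleton.mirror_pair[left]
            expect = np.linalg.norm(M @ rel[0, rows[left]] - rel[0, rows[right]])
            assert out[0, k] == pytest.approx(expect, abs=1e-9)

    def test_midline_streams_measure_own_mirror_distance(self, skeleton, rel_template):
        rows = _rows(skeleton)
        rel = rel_template.copy()
        rel[0, rows["Head"]] += np.array([0.05, 0.0, 0.0])  # off the sagittal plane
        out = symmetry_features(rel)
        hip_axis = rel[0, rows["RightHip"]] - rel[0, rows["LeftHip"]]
        n = hip_axis / np.linalg.norm(hip_axis)
        M = mirror_matrix(n)
        head = rel[0, rows["Head"]]
        k = 8 + list(skeleton.midline_joints).index("Head")
        assert out[0, k] == pytest.approx(np.linalg.norm(M @ head - head), abs=1e-9)

    def test_degenerate_hip_axis_rejected(self, skeleton, rel_template):
        rows = _rows(skeleton)
        rel = rel_template.copy()
        rel[0, rows["RightHip"]] = rel[0, rows["LeftHip"]]
        with pytest.raises(ValueError, match="hip"):
            symmetry_features(rel)


class TestExtractAll:
    def test_exactly_67_streams(self, one_session):
        ref = bc.compute_reference_lengths([one_session])
        rel, rate = bc.normalize_session(one_session, ref)
        streams = bc.extract_all(rel, rate)
        assert streams.movement.shape[1] == 30
        assert streams.pose.shape[1] == 37
        assert streams.pose.shape[0] == streams.movement.shape[0] + 1

    def test_rigid_transform_invariance(self, one_session, rng):
        """Rotating + translating the raw capture leaves all 67 streams unchanged."""
        ref = bc.compute_reference_lengths([one_session])
        rel, rate = bc.normalize_session(one_session, ref)
        base = bc.extract_all(rel, rate)
        rot = random_rotation(rng)
        moved = one_session.with_frames(
            one_session.frames @ rot.T + np.array([0.7, -1.2, 3.0])
        )
        ref2 = bc.compute_reference_lengths([moved])
        rel2, _ = bc.normalize_session(moved, ref2)
        other = bc.extract_all(rel2, rate)
        assert other.movement == pytest.approx(base.movement, abs=1e-9)
        assert other.pose == pytest.approx(base.pose, abs=1e-9)

    def test_streams_respect_sign_and_range_invariants(self, one_session):
        ref = bc.compute_reference_lengths([one_session])
        rel, rate = bc.normalize_session(one_session, ref)
        s = bc.extract_all(rel, rate)
        assert (s.movement >= 0).all()
        angles = s.pose[:, :10]
        assert ((angles >= 0) & (angles <= 180)).all()
        assert (s.pose[:, 10:] >= 0).all()
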