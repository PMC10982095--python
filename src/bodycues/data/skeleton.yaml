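# Canonical 23-joint skeleton (Xsens MVN style): axial chain plus four limbs.
# Joint order is canonical everywhere in the package: readers, arrays, features.
name: xsens23
root: Pelvis
joints:
  - Pelvis
  - L5
  - L3
  - T12
  - T8
  - Neck
  - Head
  - LeftShoulder
  - LeftElbow
  - LeftWrist
  - LeftHand
  - RightShoulder
  - RightElbow
  - RightWrist
  - RightHand
  - LeftHip
  - LeftKnee
  - LeftAnkle
  - LeftToe
  - RightHip
  - RightKnee
  - RightAnkle
  - RightToe
parent:
  L5: Pelvis
  L3: L5
  T12: L3
  T8: T12
  Neck: T8
  Head: Neck
  LeftShoulder: T8
  LeftElbow: LeftShoulder
  LeftWrist: LeftElbow
  LeftHand: LeftWrist
  RightShoulder: T8
  RightElbow: RightShoulder
  RightWrist: RightElbow
  RightHand: RightWrist
  LeftHip: Pelvis
  LeftKnee: LeftHip
  LeftAnkle: LeftKnee
  LeftToe: LeftAnkle
  RightHip: Pelvis
  RightKnee: RightHip
  RightAnkle: RightKnee
  RightToe: RightAnkle
body_part:
  L5: torso
  L3: torso
  T12: torso
  T8: torso
  Neck: head
  Head: head
  LeftShoulder: left_arm
  LeftElbow: left_arm
  LeftWrist: left_arm
  LeftHand: left_arm
  RightShoulder: right_arm
  RightElbow: right_arm
  RightWrist: right_arm
  RightHand: right_arm
  LeftHip: left_leg
  LeftKnee: left_leg
  LeftAnkle: left_leg
  LeftToe: left_leg
  RightHip: right_leg
  RightKnee: right_leg
  RightAnkle: right_leg
  RightToe: right_leg
mirror_pair:
  LeftShoulder: RightShoulder
  LeftElbow: RightElbow
  LeftWrist: RightWrist
  LeftHand: RightHand
  LeftHip: RightHip
  LeftKnee: RightKnee
  LeftAnkle: RightAnkle
  LeftToe: RightToe
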