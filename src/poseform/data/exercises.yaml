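# Seven-exercise compound-lift catalog: monitored joints with reference
# angles (degrees, evaluated at the bottom-of-rep frame), tolerance bands,
# repetition-FSM thresholds on the primary joint, and the 2-3 primary
# target muscles shown to the user.
#
# The squat preset is the fully modeled archetype (hip/knee/ankle sagittal
# chain, references 90/90/75 deg); the remaining lifts are threshold-level
# presets on their primary flexion joint.
version: 1
exercises:
  barbell_squat:
    primary_joint: knee
    angle_mode: "3d"
    joints:
      - {joint_name: hip, proximal: shoulder, vertex: hip, distal: knee,
         reference_deg: 90.0, tolerance_deg: 10.0}
      - {joint_name: knee, proximal: hip, vertex: knee, distal: ankle,
         reference_deg: 90.0, tolerance_deg: 10.0}
      - {joint_name: ankle, proximal: knee, vertex: ankle, distal: foot_index,
         reference_deg: 75.0, tolerance_deg: 10.0}
    fsm: {descent_threshold: 150.0, bottom_threshold: 100.0, hysteresis: 5.0}
    muscles: [quadriceps, gluteus maximus, hamstrings]
  bench_press:
    primary_joint: elbow
    angle_mode: "3d"
    joints:
      - {joint_name: elbow, proximal: shoulder, vertex: elbow, distal: wrist,
         reference_deg: 75.0, tolerance_deg: 12.0}
    fsm: {descent_threshold: 150.0, bottom_threshold: 100.0, hysteresis: 5.0}
    muscles: [pectoralis major, triceps brachii, anterior deltoid]
  deadlift:
    primary_joint: knee
    angle_mode: "3d"
    joints:
      - {joint_name: knee, proximal: hip, vertex: knee, distal: ankle,
         reference_deg: 120.0, tolerance_deg: 15.0}
      - {joint_name: hip, proximal: shoulder, vertex: hip, distal: knee,
         reference_deg: 90.0, tolerance_deg: 15.0}
    fsm: {descent_threshold: 160.0, bottom_threshold: 130.0, hysteresis: 5.0}
    muscles: [erector spinae, gluteus maximus, hamstrings]
  barbell_row:
    primary_joint: elbow
    angle_mode: "3d"
    joints:
      - {joint_name: elbow, proximal: shoulder, vertex: elbow, distal: wrist,
         reference_deg: 75.0, tolerance_deg: 12.0}
    fsm: {descent_threshold: 150.0, bottom_threshold: 100.0, hysteresis: 5.0}
    muscles: [latissimus dorsi, rhomboids, biceps brachii]
  military_press:
    primary_joint: elbow
    angle_mode: "3d"
    joints:
      - {joint_name: elbow, proximal: shoulder, vertex: elbow, distal: wrist,
         reference_deg: 80.0, tolerance_deg: 12.0}
    fsm: {descent_threshold: 150.0, bottom_threshold: 100.0, hysteresis: 5.0}
    muscles: [deltoids, triceps brachii, upper trapezius]
  pull_up:
    primary_joint: elbow
    angle_mode: "3d"
    joints:
      - {joint_name: elbow, proximal: shoulder, vertex: elbow, distal: wrist,
         reference_deg: 60.0, tolerance_deg: 12.0}
    fsm: {descent_threshold: 150.0, bottom_threshold: 90.0, hysteresis: 5.0}
    muscles: [latissimus dorsi, biceps brachii, teres major]
  dips:
    primary_joint: elbow
    angle_mode: "3d"
    joints:
      - {joint_name: elbow, proximal: shoulder, vertex: elbow, distal: wrist,
         reference_deg: 90.0, tolerance_deg: 12.0}
    fsm: {descent_threshold: 150.0, bottom_threshold: 105.0, hysteresis: 5.0}
    muscles: [pectoralis major, triceps brachii, anterior deltoid]
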