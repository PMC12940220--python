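# Corrective-exercise rule table: deterministic mapping from a detected
# form deficiency to one recommendation per difficulty level.  Demo clip
# durations are 10-15 s by contract.
version: 1
rules:
  insufficient_depth:
    beginner:
      exercise_name: box squat to parallel
      description: >
        Squat to a box set at parallel depth; pause briefly to groove the
        full range before standing.
      demo_duration_s: 12
    intermediate:
      exercise_name: goblet squat with pause
      description: >
        Hold a light weight at the chest and pause 2 s at the bottom to
        build depth control.
      demo_duration_s: 13
    advanced:
      exercise_name: tempo full squat
      description: >
        3-s eccentric to full depth with a controlled ascent under
        moderate load.
      demo_duration_s: 15
  knee_valgus:
    beginner:
      exercise_name: banded lateral walk
      description: >
        Mini-band above the knees; side-step keeping the knees pressed
        outward over the toes.
      demo_duration_s: 11
    intermediate:
      exercise_name: banded squat
      description: >
        Squat with a mini-band above the knees, actively driving the
        knees out against the band.
      demo_duration_s: 12
    advanced:
      exercise_name: single-leg squat to box
      description: >
        Slow single-leg squat to a box, keeping knee tracking over the
        second toe.
      demo_duration_s: 14
  trunk_lean:
    beginner:
      exercise_name: wall-facing squat
      description: >
        Squat facing a wall with toes close to it, forcing an upright
        trunk.
      demo_duration_s: 10
    intermediate:
      exercise_name: front-loaded goblet squat
      description: >
        Anterior load encourages a vertical torso; keep the elbows
        between the knees at depth.
      demo_duration_s: 12
    advanced:
      exercise_name: front squat
      description: >
        Barbell front-rack squat emphasizing thoracic extension and an
        upright trunk.
      demo_duration_s: 15
  heel_rise:
    beginner:
      exercise_name: heel-elevated squat
      description: >
        Small plates under the heels while ankle mobility develops; keep
        full foot contact.
      demo_duration_s: 10
    intermediate:
      exercise_name: ankle dorsiflexion rocks
      description: >
        Half-kneeling ankle rocks driving the knee over the toes without
        lifting the heel.
      demo_duration_s: 11
    advanced:
      exercise_name: deep tempo squat barefoot
      description: >
        Slow full-depth squats focusing on keeping the heels planted
        throughout.
      demo_duration_s: 14
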