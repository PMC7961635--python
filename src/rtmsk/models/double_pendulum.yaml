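# Planar double pendulum: two uniform 1 m rods, hinged at the ground origin
# and at the first rod's tip. Oracle model for inverse dynamics (its
# equations of motion have a tractable Lagrangian closed form).
name: double_pendulum
segments:
  - name: upper
    mass: 1.5
    inertia: [0.125, 0.00015, 0.125, 0.0, 0.0, 0.0]
    com: [0.0, -0.5, 0.0]
    endpoints:
      distal: [0.0, -1.0, 0.0]
  - name: lower
    mass: 1.0
    inertia: [0.08333333333333333, 0.0001, 0.08333333333333333, 0.0, 0.0, 0.0]
    com: [0.0, -0.5, 0.0]
    endpoints:
      distal: [0.0, -1.0, 0.0]
joints:
  - name: shoulder
    type: revolute
    parent: ground
    child: upper
    axes: [[0.0, 0.0, 1.0]]
    coordinates: [q1]
  - name: elbow
    type: revolute
    parent: upper
    child: lower
    offset_parent: [0.0, -1.0, 0.0]
    axes: [[0.0, 0.0, 1.0]]
    coordinates: [q2]
markers:
  - {name: elbow_m, segment: upper, position: [0.0, -1.0, 0.0]}
  - {name: tip_m, segment: lower, position: [0.0, -1.0, 0.0]}
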