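# Single planar pendulum: a uniform 1 m rod of 1 kg hinged at the ground
# origin, swinging in the x-y plane about the z axis. Used as an analytic
# test case (circular-motion kinematics, gravity statics).
name: pendulum
segments:
  - name: rod
    mass: 1.0
    # [xx, yy, zz, xy, xz, yz] about the COM, segment frame
    inertia: [0.08333333333333333, 0.0001, 0.08333333333333333, 0.0, 0.0, 0.0]
    com: [0.0, -0.5, 0.0]
    endpoints:
      tip: [0.0, -1.0, 0.0]
joints:
  - name: pin
    type: revolute
    parent: ground
    child: rod
    offset_parent: [0.0, 0.0, 0.0]
    offset_child: [0.0, 0.0, 0.0]
    axes: [[0.0, 0.0, 1.0]]
    coordinates: [theta]
markers:
  - {name: tip, segment: rod, position: [0.0, -1.0, 0.0]}
  - {name: mid, segment: rod, position: [0.0, -0.5, 0.0]}
  - {name: side, segment: rod, position: [0.05, -0.5, 0.0]}
imus:
  - {name: rod_imu, segment: rod}
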