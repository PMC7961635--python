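# Planar bipedal walker: 7 segments, 9 DoF (3-DoF planar base at the pelvis
# plus bilateral hip/knee/ankle pins about z). Anthropometric mass fractions
# of a 75 kg subject (trunk/head/arms lumped into the pelvis segment).
# Standing pose (q = 0) has straight legs; the ground is the y = 0 plane when
# the pelvis is raised to ty = 0.85 m. Each segment carries >= 3 non-collinear
# markers and one IMU frame; each foot has heel and metatarsophalangeal (mtp)
# endpoints; 12 straight-line muscles form an antagonist pair per joint.
name: planar_walker
segments:
  - name: pelvis
    mass: 50.85
    inertia: [1.5, 0.8, 1.5, 0.0, 0.0, 0.0]
    com: [0.0, 0.3, 0.0]
  - name: thigh_r
    mass: 7.5
    inertia: [0.1, 0.005, 0.1, 0.0, 0.0, 0.0]
    com: [0.0, -0.173, 0.0]
    endpoints: {knee: [0.0, -0.4, 0.0]}
  - name: shank_r
    mass: 3.4875
    inertia: [0.0465, 0.002, 0.0465, 0.0, 0.0, 0.0]
    com: [0.0, -0.173, 0.0]
    endpoints: {ankle: [0.0, -0.4, 0.0]}
  - name: foot_r
    mass: 1.0875
    inertia: [0.0012, 0.004, 0.0042, 0.0, 0.0, 0.0]
    com: [0.05, -0.025, 0.0]
    endpoints:
      heel: [-0.05, -0.05, 0.0]
      mtp: [0.15, -0.05, 0.0]
  - name: thigh_l
    mass: 7.5
    inertia: [0.1, 0.005, 0.1, 0.0, 0.0, 0.0]
    com: [0.0, -0.173, 0.0]
    endpoints: {knee: [0.0, -0.4, 0.0]}
  - name: shank_l
    mass: 3.4875
    inertia: [0.0465, 0.002, 0.0465, 0.0, 0.0, 0.0]
    com: [0.0, -0.173, 0.0]
    endpoints: {ankle: [0.0, -0.4, 0.0]}
  - name: foot_l
    mass: 1.0875
    inertia: [0.0012, 0.004, 0.0042, 0.0, 0.0, 0.0]
    com: [0.05, -0.025, 0.0]
    endpoints:
      heel: [-0.05, -0.05, 0.0]
      mtp: [0.15, -0.05, 0.0]
joints:
  - name: base
    type: free_planar
    parent: ground
    child: pelvis
    coordinates: [pelvis_tx, pelvis_ty, pelvis_rz]
  - name: hip_r
    type: revolute
    parent: pelvis
    child: thigh_r
    offset_parent: [0.0, 0.0, 0.1]
    coordinates: [hip_r]
  - name: knee_r
    type: revolute
    parent: thigh_r
    child: shank_r
    offset_parent: [0.0, -0.4, 0.0]
    coordinates: [knee_r]
  - name: ankle_r
    type: revolute
    parent: shank_r
    child: foot_r
    offset_parent: [0.0, -0.4, 0.0]
    coordinates: [ankle_r]
  - name: hip_l
    type: revolute
    parent: pelvis
    child: thigh_l
    offset_parent: [0.0, 0.0, -0.1]
    coordinates: [hip_l]
  - name: knee_l
    type: revolute
    parent: thigh_l
    child: shank_l
    offset_parent: [0.0, -0.4, 0.0]
    coordinates: [knee_l]
  - name: ankle_l
    type: revolute
    parent: shank_l
    child: foot_l
    offset_parent: [0.0, -0.4, 0.0]
    coordinates: [ankle_l]
markers:
  - {name: pelvis_front, segment: pelvis, position: [0.12, 0.0, 0.0]}
  - {name: pelvis_back_r, segment: pelvis, position: [-0.1, 0.02, 0.06]}
  - {name: pelvis_back_l, segment: pelvis, position: [-0.1, 0.02, -0.06]}
  - {name: pelvis_top, segment: pelvis, position: [0.0, 0.25, 0.0]}
  - {name: thigh_r_1, segment: thigh_r, position: [0.05, -0.1, 0.03]}
  - {name: thigh_r_2, segment: thigh_r, position: [-0.05, -0.2, 0.03]}
  - {name: thigh_r_3, segment: thigh_r, position: [0.05, -0.3, -0.03]}
  - {name: thigh_r_4, segment: thigh_r, position: [0.0, -0.35, 0.05]}
  - {name: shank_r_1, segment: shank_r, position: [0.04, -0.1, 0.02]}
  - {name: shank_r_2, segment: shank_r, position: [-0.04, -0.2, 0.02]}
  - {name: shank_r_3, segment: shank_r, position: [0.04, -0.3, -0.02]}
  - {name: foot_r_heel, segment: foot_r, position: [-0.05, -0.03, 0.0]}
  - {name: foot_r_toe, segment: foot_r, position: [0.15, -0.03, 0.02]}
  - {name: foot_r_lat, segment: foot_r, position: [0.05, 0.0, 0.04]}
  - {name: thigh_l_1, segment: thigh_l, position: [0.05, -0.1, -0.03]}
  - {name: thigh_l_2, segment: thigh_l, position: [-0.05, -0.2, -0.03]}
  - {name: thigh_l_3, segment: thigh_l, position: [0.05, -0.3, 0.03]}
  - {name: thigh_l_4, segment: thigh_l, position: [0.0, -0.35, -0.05]}
  - {name: shank_l_1, segment: shank_l, position: [0.04, -0.1, -0.02]}
  - {name: shank_l_2, segment: shank_l, position: [-0.04, -0.2, -0.02]}
  - {name: shank_l_3, segment: shank_l, position: [0.04, -0.3, 0.02]}
  - {name: foot_l_heel, segment: foot_l, position: [-0.05, -0.03, 0.0]}
  - {name: foot_l_toe, segment: foot_l, position: [0.15, -0.03, -0.02]}
  - {name: foot_l_lat, segment: foot_l, position: [0.05, 0.0, -0.04]}
imus:
  - {name: pelvis_imu, segment: pelvis}
  - {name: thigh_r_imu, segment: thigh_r}
  - {name: shank_r_imu, segment: shank_r}
  - {name: foot_r_imu, segment: foot_r}
  - {name: thigh_l_imu, segment: thigh_l}
  - {name: shank_l_imu, segment: shank_l}
  - {name: foot_l_imu, segment: foot_l}
muscles:
  - name: hip_flex_r
    fmax: 3000.0
    path: [[pelvis, 0.07, 0.05, 0.1], [thigh_r, 0.03, -0.15, 0.0]]
  - name: hip_ext_r
    fmax: 3000.0
    path: [[pelvis, -0.07, 0.05, 0.1], [thigh_r, -0.03, -0.15, 0.0]]
  - name: knee_ext_r
    fmax: 3000.0
    path: [[thigh_r, 0.04, -0.25, 0.0], [shank_r, 0.04, -0.1, 0.0]]
  - name: knee_flex_r
    fmax: 3000.0
    path: [[thigh_r, -0.04, -0.25, 0.0], [shank_r, -0.04, -0.1, 0.0]]
  - name: ankle_dorsi_r
    fmax: 2000.0
    path: [[shank_r, 0.035, -0.25, 0.0], [foot_r, 0.1, -0.04, 0.0]]
  - name: ankle_plantar_r
    fmax: 2000.0
    path: [[shank_r, -0.035, -0.25, 0.0], [foot_r, -0.05, -0.04, 0.0]]
  - name: hip_flex_l
    fmax: 3000.0
    path: [[pelvis, 0.07, 0.05, -0.1], [thigh_l, 0.03, -0.15, 0.0]]
  - name: hip_ext_l
    fmax: 3000.0
    path: [[pelvis, -0.07, 0.05, -0.1], [thigh_l, -0.03, -0.15, 0.0]]
  - name: knee_ext_l
    fmax: 3000.0
    path: [[thigh_l, 0.04, -0.25, 0.0], [shank_l, 0.04, -0.1, 0.0]]
  - name: knee_flex_l
    fmax: 3000.0
    path: [[thigh_l, -0.04, -0.25, 0.0], [shank_l, -0.04, -0.1, 0.0]]
  - name: ankle_dorsi_l
    fmax: 2000.0
    path: [[shank_l, 0.035, -0.25, 0.0], [foot_l, 0.1, -0.04, 0.0]]
  - name: ankle_plantar_l
    fmax: 2000.0
    path: [[shank_l, -0.035, -0.25, 0.0], [foot_l, -0.05, -0.04, 0.0]]
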