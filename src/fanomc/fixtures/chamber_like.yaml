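phantom:
  name: phantom_water
  center:
  - 0.0
  - 0.0
  - 0.0
  size:
  - 10.0
  - 10.0
  - 12.0
  density: 1.0
regions:
- name: wall_pmma
  density: 1.19
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.4
  z:
  - -0.5
  - 2.5
- name: liner_graphite
  density: 1.7
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.33
  z:
  - -0.43
  - 0.3
- name: cavity_air
  density: 0.0012048
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.3006771825919975
  z:
  - -0.4
  - -0.15
- name: electrode_al
  density: 2.7
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.04
  z:
  - -0.38
  - -0.18
- name: stem_gap_1
  density: 0.0012048
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.25
  z:
  - 0.6
  - 0.64
- name: stem_gap_2
  density: 0.0012048
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.25
  z:
  - 1.2
  - 1.24
- name: stem_gap_3
  density: 0.0012048
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.25
  z:
  - 1.8
  - 1.84
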