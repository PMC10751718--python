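phantom:
  name: phantom_water
  center:
  - 0.0
  - 0.0
  - 0.0
  size:
  - 4.0
  - 4.0
  - 4.0
  density: 1.0
regions:
- name: water_upstream
  density: 1.0
  shape: box
  center:
  - 0.0
  - 0.0
  - -0.3
  size:
  - 1.2
  - 1.2
  - 0.4
- name: gap
  density: 0.0012048
  shape: box
  center:
  - 0.0
  - 0.0
  - 0.0
  size:
  - 1.2
  - 1.2
  - 0.2
- name: water_downstream
  density: 1.0
  shape: box
  center:
  - 0.0
  - 0.0
  - 0.3
  size:
  - 1.2
  - 1.2
  - 0.4
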