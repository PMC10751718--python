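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
- name: housing_pmma
  density: 1.19
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.35
  z:
  - -0.8
  - 0.8
- name: epoxy
  density: 1.2
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.25
  z:
  - -0.5
  - 0.5
- name: air_gap
  density: 0.0012048
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.2
  z:
  - 0.1
  - 0.16
- name: chip_si
  density: 2.33
  shape: cylinder
  center:
  - 0.0
  - 0.0
  radius: 0.10403141895720198
  z:
  - -0.005
  - 0.005
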