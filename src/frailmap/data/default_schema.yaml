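items:
- name: deficit_001
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_002
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_003
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_004
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_005
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_006
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_007
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_008
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_009
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_010
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_011
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_012
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_013
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_014
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_015
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_016
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_017
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_018
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_019
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_020
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_021
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_022
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_023
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_024
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_025
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_026
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_027
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_028
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_029
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
- name: deficit_030
  kind: binary
  mapping:
    0.0: 0.0
    1.0: 1.0
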