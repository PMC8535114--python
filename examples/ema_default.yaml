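# Default ten-coil actuation layout: Helmholtz pair (z), Maxwell
# pairs (x, y), rectangular pairs on the horizontal diagonals.
# Pass to any CLI subcommand with --config.
ema:
  coils:
  - shape: circular
    center:
    - 0.0
    - 0.0
    - 0.145
    axis:
    - 0.0
    - 0.0
    - 1.0
    turns: 500
    label: HH_z+
    radius: 0.25
  - shape: circular
    center:
    - 0.0
    - 0.0
    - -0.105
    axis:
    - 0.0
    - 0.0
    - 1.0
    turns: 500
    label: HH_z-
    radius: 0.25
  - shape: circular
    center:
    - 0.21650635094610965
    - 0.0
    - 0.02
    axis:
    - 1.0
    - 0.0
    - 0.0
    turns: 500
    label: MW_x+
    radius: 0.25
  - shape: circular
    center:
    - -0.21650635094610965
    - 0.0
    - 0.02
    axis:
    - 1.0
    - 0.0
    - 0.0
    turns: 500
    label: MW_x-
    radius: 0.25
  - shape: circular
    center:
    - 0.0
    - 0.21650635094610965
    - 0.02
    axis:
    - 0.0
    - 1.0
    - 0.0
    turns: 500
    label: MW_y+
    radius: 0.25
  - shape: circular
    center:
    - 0.0
    - -0.21650635094610965
    - 0.02
    axis:
    - 0.0
    - 1.0
    - 0.0
    turns: 500
    label: MW_y-
    radius: 0.25
  - shape: rectangular
    center:
    - 0.21213203435596423
    - 0.21213203435596423
    - 0.02
    axis:
    - 0.7071067811865475
    - 0.7071067811865475
    - 0.0
    turns: 300
    label: RC_d1+
    half_width: 0.15
    half_height: 0.1
  - shape: rectangular
    center:
    - -0.21213203435596423
    - -0.21213203435596423
    - 0.02
    axis:
    - 0.7071067811865475
    - 0.7071067811865475
    - 0.0
    turns: 300
    label: RC_d1-
    half_width: 0.15
    half_height: 0.1
  - shape: rectangular
    center:
    - 0.18371173070873834
    - -0.18371173070873834
    - 0.16999999999999996
    axis:
    - 0.6123724356957945
    - -0.6123724356957945
    - 0.49999999999999994
    turns: 300
    label: RC_d2+
    half_width: 0.15
    half_height: 0.1
  - shape: rectangular
    center:
    - -0.18371173070873834
    - 0.18371173070873834
    - -0.12999999999999998
    axis:
    - 0.6123724356957945
    - -0.6123724356957945
    - 0.49999999999999994
    turns: 300
    label: RC_d2-
    half_width: 0.15
    half_height: 0.1
  roi:
    lo:
    - -0.05
    - -0.05
    - 0.0
    hi:
    - 0.05
    - 0.05
    - 0.04
  current_limit: 30.0
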