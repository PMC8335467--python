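# PACE-C dose criteria for 40 Gy in 5 fractions (course-level evaluation).
#
# metric: V  -> volume receiving >= threshold_gy, in `unit` (cc or pct)
#         D  -> minimum dose (Gy) to the hottest `volume_pct` of the structure
# direction: lower -> criterion met when measured value >= bound
#            upper -> criterion met when measured value <  bound (strict read:
#            a value exactly equal to the bound is not exceeded)
# minor_band: values on the failing side still rated an acceptable minor
#            variation rather than a violation
# in_penalty: contributes to the penalty score S (the four scoring criteria)
criteria:
  - name: ctv_v40
    structure: ctv
    metric: V
    threshold_gy: 40.0
    unit: pct
    bound: 95.0
    direction: lower
    minor_band: [90.0, 94.9]
    in_penalty: false
  - name: ptv_v36.25
    structure: ptv
    metric: V
    threshold_gy: 36.25
    unit: pct
    bound: 95.0
    direction: lower
    minor_band: [90.0, 94.9]
    in_penalty: true
  - name: ptv_d98
    structure: ptv
    metric: D
    volume_pct: 98.0
    bound: 34.4
    direction: lower
    in_penalty: true
  - name: rectum_v36
    structure: rectum
    metric: V
    threshold_gy: 36.0
    unit: cc
    bound: 2.0
    direction: upper
    in_penalty: true
  - name: rectum_v29
    structure: rectum
    metric: V
    threshold_gy: 29.0
    unit: pct
    bound: 20.0
    direction: upper
    in_penalty: false
  - name: rectum_v18.1
    structure: rectum
    metric: V
    threshold_gy: 18.1
    unit: pct
    bound: 50.0
    direction: upper
    in_penalty: false
  - name: bladder_v37
    structure: bladder
    metric: V
    threshold_gy: 37.0
    unit: cc
    bound: 10.0
    direction: upper
    in_penalty: true
  - name: bladder_v18.1
    structure: bladder
    metric: V
    threshold_gy: 18.1
    unit: pct
    bound: 40.0
    direction: upper
    in_penalty: false
  - name: bowel_v18.1
    structure: bowel
    metric: V
    threshold_gy: 18.1
    unit: cc
    bound: 5.0
    direction: upper
    in_penalty: false
    optional: true
  - name: bowel_v30
    structure: bowel
    metric: V
    threshold_gy: 30.0
    unit: cc
    bound: 1.0
    direction: upper
    in_penalty: false
    optional: true
  - name: femoral_heads_v14.5
    structure: femoral_heads
    metric: V
    threshold_gy: 14.5
    unit: pct
    bound: 5.0
    direction: upper
    in_penalty: false
    optional: true
  - name: penile_bulb_v29.5
    structure: penile_bulb
    metric: V
    threshold_gy: 29.5
    unit: pct
    bound: 50.0
    direction: upper
    in_penalty: false
    optional: true
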