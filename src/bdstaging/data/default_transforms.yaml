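# Default transform registry: one entry per profiler.
# Reproduces bdstaging.transforms.default_registry() bit-exactly.
transforms:
  - name: hosp_n
    kind: capped_count
    cap: 6
  - name: suic_att_n
    kind: capped_count
    cap: 6
  - name: com_pd
    kind: binary
  - name: bmi
    kind: categorical_bmi
    bmi_edges: [25.0, 30.0]
    bmi_values: [0.0, 0.5, 1.0]
  - name: mets
    kind: binary
  - name: illness_n
    kind: capped_count
    cap: 4
  - name: scip_cat
    kind: ordinal_map
    level_map:
      none: 0.0
      mild: 0.3333333333333333
      moderate: 0.6666666666666666
      severe: 1.0
  - name: pd_x_bd
    kind: binary
  - name: fast_total
    kind: linear_rescale
    lo: 0.0
    hi: 72.0
  - name: fast_leisure
    kind: linear_rescale
    lo: 0.0
    hi: 6.0
  - name: sf_pf
    kind: z_linear_clip
    z_best: 3.0
    z_worst: -3.0
  - name: sf_mh
    kind: z_linear_clip
    z_best: 3.0
    z_worst: -3.0
cutoffs: [1.70, 2.50, 4.50, 6.10]
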