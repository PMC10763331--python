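# Five pathway scenarios applied on top of the shared setup
# (methanol uptake 10 mmol/gDW/h, objective = product exchange).
# "calibrate:max"/"calibrate:min" recompute the extreme feasible flux of
# the aliased reaction on the current model before forcing the bound.
scenarios:
  - name: Ref
    description: unconstrained reference
    edits: []
  - name: TCA-
    description: blocked circular TCA flux
    edits:
      - {alias: PDHa1,    which: upper, value: 0}
      - {alias: PDHcm,    which: upper, value: 0}
      - {alias: ACLSm,    which: upper, value: 0}
      - {alias: AKGDH1+2, which: upper, value: 0}
      - {alias: CITtam,   which: upper, value: 0}
      - {alias: CITtap,   which: upper, value: 0}
      - {alias: CSp+m,    which: upper, value: 0}
  - name: TCA+
    description: forced circular TCA flux
    edits:
      - {alias: AKGDam, which: lower, value: "calibrate:max"}
  - name: GlxStd
    description: forced standard glyoxylate shunt
    edits:
      - {alias: ICL, which: lower, value: "calibrate:max"}
  - name: GlxVar
    description: forced glyoxylate shunt with impaired mitochondrial MDH
    edits:
      - {alias: ICL,  which: lower, value: "calibrate:max"}
      - {alias: MDHm, which: lower, value: -10}
      - {alias: MDHm, which: upper, value: "calibrate:min"}
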