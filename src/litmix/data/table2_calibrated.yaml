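# Calibrated single-litter parameters for the peatland case study:
# Sphagnum rubellum (wet, slow-evaporating bryophyte) and Molinia caerulea
# (dry, fast-evaporating gramineae). Bunnell moisture model throughout;
# c and d sit at their upper bound (the litter's saturation capacity).
litters:
  - name: sphagnum_rubellum
    lwc_max: 22
    k_max: 0.0055
    e: 0.010
    model_kind: bunnell
    c: 22
    d: 22
  - name: molinia_caerulea
    lwc_max: 3
    k_max: 0.0060
    e: 0.061
    model_kind: bunnell
    c: 3
    d: 3
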