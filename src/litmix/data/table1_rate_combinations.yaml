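# Rate Combinations experiment (bunnell model only): the wet litter holds
# more water at saturation but decomposes slowly; the dry litter the
# opposite. Simulation 1 ("identical within litter") pairs the slow
# decomposer with slow evaporation; simulation 2 ("different within litter")
# swaps the evaporation rates.
litters:
  - name: WET-LIT-sim1
    lwc_max: 15
    k_max: 0.005
    e: 0.01
    model_kind: bunnell
    c: 10
    d: 5
  - name: DRY-LIT-sim1
    lwc_max: 5
    k_max: 0.015
    e: 0.1
    model_kind: bunnell
    c: 1
    d: 5
  - name: WET-LIT-sim2
    lwc_max: 15
    k_max: 0.005
    e: 0.1
    model_kind: bunnell
    c: 10
    d: 5
  - name: DRY-LIT-sim2
    lwc_max: 5
    k_max: 0.015
    e: 0.01
    model_kind: bunnell
    c: 1
    d: 5
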