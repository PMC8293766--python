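# Model Comparison experiment: identical moisture sensitivity and saturation
# capacity for both litters; only the evaporation rate differs (slow for the
# wet litter, fast for the dry one). One litter pair per moisture model.
litters:
  - name: WET-LIT-moyano
    lwc_max: 10
    k_max: 0.01
    e: 0.01
    model_kind: moyano
    a: 5
    b: 0.5
  - name: DRY-LIT-moyano
    lwc_max: 10
    k_max: 0.01
    e: 0.1
    model_kind: moyano
    a: 5
    b: 0.5
  - name: WET-LIT-bunnell
    lwc_max: 10
    k_max: 0.01
    e: 0.01
    model_kind: bunnell
    c: 5
    d: 5
  - name: DRY-LIT-bunnell
    lwc_max: 10
    k_max: 0.01
    e: 0.1
    model_kind: bunnell
    c: 5
    d: 5
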