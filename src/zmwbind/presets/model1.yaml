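# Single binding step: U1 <-> B1
model_id: 1
states:
  - {label: U1, class: unbound}
  - {label: B1, class: bound}
transitions:
  - {from: U1, to: B1, rate: "U1->B1", binding: true,  value: 1.3e5}
  - {from: B1, to: U1, rate: "B1->U1", binding: false, value: 0.34}
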