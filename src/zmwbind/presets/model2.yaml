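# Binding followed by bound-state isomerization: U1 <-> B1 <-> B2
model_id: 2
states:
  - {label: U1, class: unbound}
  - {label: B1, class: bound}
  - {label: B2, class: bound}
transitions:
  - {from: U1, to: B1, rate: "U1->B1", binding: true,  value: 1.4e5}
  - {from: B1, to: U1, rate: "B1->U1", binding: false, value: 0.91}
  - {from: B1, to: B2, rate: "B1->B2", binding: false, value: 0.52}
  - {from: B2, to: B1, rate: "B2->B1", binding: false, value: 0.31}
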