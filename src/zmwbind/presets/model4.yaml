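# Linear four-state chain U2 - U1 - B1 - B2: unbound and bound isomerization
model_id: 4
states:
  - {label: U2, class: unbound}
  - {label: U1, class: unbound}
  - {label: B1, class: bound}
  - {label: B2, class: bound}
transitions:
  - {from: U1, to: B1, rate: "U1->B1", binding: true,  value: 2.3e5}
  - {from: B1, to: U1, rate: "B1->U1", binding: false, value: 0.95}
  - {from: B1, to: B2, rate: "B1->B2", binding: false, value: 0.51}
  - {from: B2, to: B1, rate: "B2->B1", binding: false, value: 0.31}
  - {from: U1, to: U2, rate: "U1->U2", binding: false, value: 0.04}
  - {from: U2, to: U1, rate: "U2->U1", binding: false, value: 0.15}
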