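# Linear six-state chain U3 - U2 - U1 - B1 - B2 - B3
model_id: 7
states:
  - {label: U3, class: unbound}
  - {label: U2, class: unbound}
  - {label: U1, class: unbound}
  - {label: B1, class: bound}
  - {label: B2, class: bound}
  - {label: B3, class: bound}
transitions:
  - {from: U1, to: B1, rate: "U1->B1", binding: true,  value: 2.8e5}
  - {from: B1, to: U1, rate: "B1->U1", binding: false, value: 1.11}
  - {from: B1, to: B2, rate: "B1->B2", binding: false, value: 0.85}
  - {from: B2, to: B1, rate: "B2->B1", binding: false, value: 0.56}
  - {from: U1, to: U2, rate: "U1->U2", binding: false, value: 0.17}
  - {from: U2, to: U1, rate: "U2->U1", binding: false, value: 0.55}
  - {from: U2, to: U3, rate: "U2->U3", binding: false, value: 0.02}
  - {from: U3, to: U2, rate: "U3->U2", binding: false, value: 0.07}
  - {from: B2, to: B3, rate: "B2->B3", binding: false, value: 0.03}
  - {from: B3, to: B2, rate: "B3->B2", binding: false, value: 0.08}
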