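# Triangle: binding to either bound conformation, U1-B1-B2-U1
model_id: 3
states:
  - {label: U1, class: unbound}
  - {label: B1, class: bound}
  - {label: B2, class: bound}
transitions:
  - {from: U1, to: B1, rate: "U1->B1", binding: true,  value: 1.3e5}
  - {from: B1, to: U1, rate: "B1->U1", binding: false, value: 0.98}
  - {from: B1, to: B2, rate: "B1->B2", binding: false, value: 0.49}
  - {from: B2, to: B1, rate: "B2->B1", binding: false, value: 0.23}
  - {from: U1, to: B2, rate: "U1->B2", binding: true,  value: 0.10e5}
  - {from: B2, to: U1, rate: "B2->U1", binding: false, value: 0.04}
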