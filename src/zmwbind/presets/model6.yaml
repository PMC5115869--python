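# Square (cycle) with binding to the isomerized unbound state: U2 <-> B2 edge
model_id: 6
states:
  - {label: U2, class: unbound}
  - {label: U1, class: unbound}
  - {label: B1, class: bound}
  - {label: B2, class: bound}
transitions:
  - {from: U1, to: B1, rate: "U1->B1", binding: true,  value: 2.4e5}
  - {from: B1, to: U1, rate: "B1->U1", binding: false, value: 1.00}
  - {from: B1, to: B2, rate: "B1->B2", binding: false, value: 0.48}
  - {from: B2, to: B1, rate: "B2->B1", binding: false, value: 0.27}
  - {from: U1, to: U2, rate: "U1->U2", binding: false, value: 0.01}
  - {from: U2, to: U1, rate: "U2->U1", binding: false, value: 0.04}
  - {from: U2, to: B2, rate: "U2->B2", binding: true,  value: 0.24e5}
  - {from: B2, to: U2, rate: "B2->U2", binding: false, value: 0.02}
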