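X1:
  direction: cost
  cost_reference: 100000
  cotrend_method: reciprocal
X2:
  direction: benefit
X3:
  direction: benefit
X4:
  direction: benefit
X5:
  direction: benefit
X6:
  direction: benefit
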