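# Online marketplace task: three products, sigma in {0, 1.5, 3.5},
# emission noise eta = 3, prices bounded 0-40 from a start of 20.
name: exp3
r0: 20.0
lower: 0.0
upper: 40.0
n_learning_trials: 240
delays_weeks: [1, 4, 9, 13]
elicitation: adaptive_staircase
conditions:
  - label: no_volatility
    sigma: 0.0
    eta: 3.0
  - label: low_volatility
    sigma: 1.5
    eta: 3.0
  - label: high_volatility
    sigma: 3.5
    eta: 3.0
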