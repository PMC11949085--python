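# Scanner marketplace task: stable product (constant price, announced)
# and volatile product (random walk, sigma = 3.5), both with emission
# noise eta = 2, prices bounded 0-50 from a start of 25.
name: exp2
r0: 25.0
lower: 0.0
upper: 50.0
n_learning_trials: 240   # per-phase trial count not printed; default
delays_weeks: [0, 1, 4, 17]
elicitation: binary_set
conditions:
  - label: stable
    sigma: 0.0
    eta: 2.0
  - label: volatile
    sigma: 3.5
    eta: 2.0
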