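# Lab marketplace task: three products with different price volatility.
# Prices bounded 0-25; per-product sigma and eta are not published for
# this design, so the values below are assumptions mirroring the online
# replication's levels (sigma in {0, 1.5, 3.5}, eta = 3).
name: exp1
r0: 12.5
lower: 0.0
upper: 25.0
n_learning_trials: 240
n_prediction_trials: 70
delays_weeks: [1, 4, 7, 12, 18]
elicitation: direct_indifference
assumed_fields: [sigma, eta, r0]   # supplement values unavailable
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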