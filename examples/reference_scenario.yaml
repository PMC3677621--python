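# Built-in benchmark: slow demographic renewal, infectious latent class (q = 1),
# nearly ineffective vaccination. R0 ~ 10; stable endemic point at small i.
parameters:
  b: 0.00001
  alpha: 0.002
  beta: 0.05
  gamma: 0.003
  epsilon: 0.05
  q: 1.0
  sigma_a: 0.000001
initial_state:
  s: 0.9
  e: 0.05
  i: 0.05
solver:
  method: RK45
  rtol: 1.0e-8
  atol: 1.0e-10
  t_end: 1.0e6
  n_samples: 10001
analysis:
  i_min: 0.0
  i_max: 1.0
  prominence_fraction: 0.01
  sustained_low: 0.9
  sustained_high: 1.1
seed: 0
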