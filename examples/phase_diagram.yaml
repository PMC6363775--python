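# (beta, sigma) phase scan at small capacity; run with
#   pggdyn phase --config examples/phase_diagram.yaml --out out/phase
params:
  alpha_C: 1.0
  alpha_D: 1.0
  delta_C: 0.05
  delta_D: 0.05
  kappa: 0.1
  K: 100
  n: 5
beta_grid: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0]
sigma_grid: [0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0]
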