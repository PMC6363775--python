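# compartment-number sweep in the weak-benefit (beta < sigma) regime; run with
#   pggdyn compartments --config examples/compartment_sweep.yaml --out out/sweep --seed 1
params:
  alpha_C: 1.0
  alpha_D: 1.0
  delta_C: 0.1
  delta_D: 0.1
  kappa: 0.5
  K: 1000
  beta: 2.0
  sigma: 3.0
  n: 10            # placeholder; neighborhoods emerge from compartment occupancy
init: [50, 50]
T_s: 10.0
n_cycles: 150
N_values: [4, 8, 16, 32, 64, 128]
replicates: 3
reinitialize: true
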