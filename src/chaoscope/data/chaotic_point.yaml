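# Fixed parameter vector and initial state of the reference chaotic input
# vector for the four-part topology (single QS inducing two bacteriocins).
# The source table lists K_A1B1 twice; the second entry is the half-max
# constant of the second bacteriocin's cassette and is stored as K_A1B2.
parameters:
  C_N: 1.0e+9
  C_B: 1.0e-9
  C_A: 1.0e-9
  D: 0.167
  K_A1B1: 3.37e-9
  K_A1B2: 4.26e-8
  K: 3.9e-5
  K_omega: 1.6e-7
  S0: 0.02
  gamma: 1.0e+11
  kA_1: 3.5e-17
  KB_max_1: 3.58e-17
  KB_max_2: 8.89e-16
  mu_max_1: 2.61
  mu_max_2: 1.17
  mu_max_3: 1.48
  n_1: 1.2
  n_2: 1.43
  n_omega: 1.87
  omega_max: 0.79
initial_state:
  N_1: 0.24
  N_2: 0.25
  N_3: 0.27
  S: 0.02
  B_1: 1.0e-71
  B_2: 1.0e-71
  A_1: 1.0e-10
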