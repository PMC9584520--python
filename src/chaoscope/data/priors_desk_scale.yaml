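# Desk-scale prior: the Table-style uniform prior narrowed to the
# neighbourhood of the known chaotic operating point of the four-part
# reference topology.  Used by the reduced-compute demonstrations of ABC
# SMC model selection (a workstation cannot afford the cluster-scale
# rejection sampling the full prior requires).
parameters:
  C_N:       {min: 1.0e+9,  max: 1.0e+9}
  C_B:       {min: 1.0e-9,  max: 1.0e-9}
  C_A:       {min: 1.0e-9,  max: 1.0e-9}
  D:         {min: 0.1,     max: 0.3}
  K_AB:      {min: 1.0e-9,  max: 1.0e-7, scale: log10}
  K:         {min: 3.9e-5,  max: 3.9e-5}
  K_omega:   {min: 1.0e-7,  max: 1.0e-6, scale: log10}
  S0:        {min: 0.02,    max: 0.02}
  gamma:     {min: 1.0e+11, max: 1.0e+11}
  kA:        {min: 7.0e-18, max: 1.75e-16, scale: log10}
  KB_max:    {min: 1.0e-17, max: 1.0e-15, scale: log10}
  mu_max:    {min: 1.0,     max: 3.0}
  n_z:       {min: 1.0,     max: 2.0}
  n_omega:   {min: 1.0,     max: 2.0}
  omega_max: {min: 0.5,     max: 2.0}
initial_state:
  N: {min: 0.01,    max: 0.5}
  S: {min: 0.02,    max: 0.02}
  B: {min: 1.0e-81, max: 1.0e-81}
  A: {min: 1.0e-10, max: 1.0e-10}
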