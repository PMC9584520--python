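# Uniform prior bounds for the three-strain chemostat community models.
# Constant parameters have min == max.  "scale: log10" marks ranges spanning
# several decades that are sampled log-uniformly by default.
parameters:
  C_N:       {min: 1.0e+9,  max: 1.0e+9,  units: "cells/OD"}
  C_B:       {min: 1.0e-9,  max: 1.0e-9,  units: ""}
  C_A:       {min: 1.0e-9,  max: 1.0e-9,  units: ""}
  D:         {min: 0.01,    max: 0.5,     units: "1/h"}
  K_AB:      {min: 1.0e-9,  max: 1.0e-6,  units: "M", scale: log10}
  K:         {min: 3.9e-5,  max: 3.9e-5,  units: "M"}
  K_omega:   {min: 1.0e-7,  max: 1.0e-6,  units: "M", scale: log10}
  S0:        {min: 0.02,    max: 0.02,    units: "M"}
  gamma:     {min: 1.0e+11, max: 1.0e+11, units: "cells/M"}
  kA:        {min: 1.0e-22, max: 1.0e-15, units: "M/h per cell", scale: log10}
  KB_max:    {min: 1.0e-22, max: 1.0e-15, units: "M/h per cell", scale: log10}
  mu_max:    {min: 0.4,     max: 3.0,     units: "1/h"}
  n_z:       {min: 1.0,     max: 2.0,     units: ""}
  n_omega:   {min: 1.0,     max: 2.0,     units: ""}
  omega_max: {min: 0.5,     max: 2.0,     units: "1/h"}
initial_state:
  N: {min: 0.01,    max: 0.5,     units: "OD"}
  S: {min: 0.02,    max: 0.02,    units: "M"}
  B: {min: 1.0e-81, max: 1.0e-81, units: "scaled"}
  A: {min: 1.0e-10, max: 1.0e-10, units: "scaled"}
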