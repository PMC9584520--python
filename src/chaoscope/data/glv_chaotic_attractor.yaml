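# Four-species competitive gLV chaotic attractor (brute-force parameter
# search by Vano et al.); the interaction matrix diagonal plays the role of
# a uniform self-limitation / dilution term.
r: [1.0, 0.72, 1.53, 1.27]
alpha:
  - [1.0,  1.09, 1.52, 0.0]
  - [0.0,  1.0,  0.44, 1.36]
  - [2.33, 0.0,  1.0,  0.47]
  - [1.21, 0.51, 0.35, 1.0]
initial_state: [0.3013, 0.4586, 0.1307, 0.3557]
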