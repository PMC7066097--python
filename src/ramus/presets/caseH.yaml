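# Spherical-head validation case (H)
case_id: H
modality: EMEG
sparsity: 8
n_decompositions: 100
hyperprior: inverse_gamma
deep_amplitude: 10.0
superficial_amplitude: 5.0
noise_pct: 3.0
n_realizations: 50
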