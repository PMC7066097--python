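# Spherical-head validation case (F)
case_id: F
modality: EEG
sparsity: 8
n_decompositions: 20
hyperprior: inverse_gamma
deep_amplitude: 10.0
superficial_amplitude: 7.0
noise_pct: 3.0
n_realizations: 50
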