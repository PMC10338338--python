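{
  "feedback": {
    "tau_cdk46": 0.25,
    "k_phos": 4.0,
    "k_dephos": 2.0,
    "J_phos": 0.05,
    "J_dephos": 0.05,
    "k_e2f": 1.0,
    "d_e2f": 0.5,
    "K_rp": 0.6,
    "n_rp": 4.0,
    "k_cdk2": 1.2,
    "d_cdk2": 1.0
  },
  "feedforward": {
    "tau_cdk46": 0.25,
    "tau_repressor": 0.5,
    "K_cdk46": 0.5,
    "n_cdk46": 4.0,
    "mrna_half_life": 2.0,
    "protein_half_life": 12.0,
    "K_cdk2": 0.15,
    "tau_cdk2": 0.25,
    "K_rb": 0.5,
    "n_rb": 4.0,
    "tau_rb": 0.5
  }
}
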