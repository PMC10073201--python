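{
  "tau_a": 25.7,
  "tau_n": 22.5,
  "tau_v": 23.4,
  "K_an": 0.031,
  "K_na": 0.041,
  "K_av": -0.045,
  "K_va": -0.007,
  "K_nv": 0.0,
  "K_vn": 0.0,
  "gamma": 0.77
}
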