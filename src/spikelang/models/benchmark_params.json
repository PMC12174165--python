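{
  "neuron": null,
  "synapse": {
    "lambda_p": 0.0,
    "lambda_d": 0.0,
    "tau_p": 20.0,
    "tau_d": 20.0
  },
  "w_exc": 14.0,
  "g": 5.0,
  "delay": 1.5,
  "nu_ext": 39200.0,
  "w_ext": 14.0
}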