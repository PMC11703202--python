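{
  "description": "Reference parameter set of the two-ODE cyclin B-Cdk1 oscillator. Hill response shapes follow the experimentally measured ultrasensitive steady-state responses of APC/C, Cdc25 and Wee1 to Cdk1 activity in cycling frog egg extracts; kinetic scales are calibrated once so the limit-cycle period at the reference temperature is ~30 min.",
  "t_ref_c": 20.0,
  "rates": {
    "ks": 1.2,
    "kd": 0.08,
    "ka": 1.0,
    "ki": 1.0,
    "eps": 0.01
  },
  "hill": {
    "deg": {
      "basal": 0.02,
      "amplitude": 0.98,
      "ec50": 32.0,
      "hill_n": 17.0,
      "direction": "increasing"
    },
    "cdc25": {
      "basal": 0.16,
      "amplitude": 0.8,
      "ec50": 35.0,
      "hill_n": 11.0,
      "direction": "increasing"
    },
    "wee1": {
      "basal": 0.08,
      "amplitude": 0.4,
      "ec50": 30.0,
      "hill_n": 3.5,
      "direction": "decreasing"
    }
  }
}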