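{
 "k0": {
  "k1": 6154699990.849551,
  "k2": 9999798384.622578,
  "k3": 95263499.51210216,
  "k4": 9999999999.832628,
  "k5": 24903423.999552663,
  "k6": 33958648.66944007,
  "k7": 273902074.16934955,
  "k8": 2032728.3433869786,
  "k9": 981082838.5062299,
  "k10": 30527068.835994817
 },
 "z": {
  "k1": 0.0,
  "k2": 0.0,
  "k3": 0.2,
  "k4": -0.2,
  "k5": 0.3,
  "k6": 0.2,
  "k7": 0.2,
  "k8": -0.2,
  "k9": 0.1,
  "k10": -0.1
 }
}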