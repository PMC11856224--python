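{
  "description": "Ratkowsky-1 curve for colony growth at constant 10-35 C (published fit, growth experiment 1)",
  "model_id": "ratkowsky1",
  "cc": 0.089,
  "k1": 2.620,
  "k2": 0.435,
  "T1": 3.926,
  "T2": 34.845
}
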