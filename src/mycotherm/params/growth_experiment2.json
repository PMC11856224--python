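{
  "description": "Ratkowsky-2 curve for colony growth at constant 27-33 C (published fit, growth experiment 2)",
  "model_id": "ratkowsky2",
  "cc": 5.919,
  "k": 0.177,
  "T1": 22.907,
  "T2": 33.250
}
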