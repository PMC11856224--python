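{
  "description": "Ratkowsky-2 curve for colony growth at constant 26-30 C (published fit, growth experiment 3)",
  "model_id": "ratkowsky2",
  "cc": 3.670,
  "k": 0.410,
  "T1": 19.634,
  "T2": 31.671
}
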