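{
  "description": "Ratkowsky-1 curve for 7-day nymphal mortality of Bemisia tabaci by Cordyceps javanica BRM 27666 at constant temperatures (published fit)",
  "model_id": "ratkowsky1",
  "cc": 2.999,
  "k1": 0.084,
  "k2": 0.090,
  "T1": 16.502,
  "T2": 36.051
}
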