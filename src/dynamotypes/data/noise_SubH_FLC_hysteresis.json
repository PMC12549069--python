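{
 "dynamotype": "SubH/FLC",
 "method": "hysteresis",
 "band": [
  0.05,
  0.1
 ],
 "nrep": 10,
 "base_seed": 2000,
 "below_band_flags": [
  true,
  true,
  true,
  true,
  true
 ]
}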