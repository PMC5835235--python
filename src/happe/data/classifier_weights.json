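{
 "weights": [
  1.9560844263562411,
  -3.549882865082432,
  -2.0540905259916933,
  -0.11648257076431151,
  0.7315118758926278,
  2.0349539757716224
 ],
 "bias": 2.4651742022308274,
 "feature_means": [
  0.8663331541795694,
  -2.7824387518212608,
  1.0767151458136772,
  0.2581174181308369,
  -0.26788373894593237,
  -1.9752952415851124
 ],
 "feature_stds": [
  1.305881945826873,
  0.8151790752623365,
  1.0592258464038704,
  0.49954786268650503,
  0.2596722089899678,
  0.24063443995348682
 ],
 "training_seeds": [
  7001,
  7002,
  7003,
  7004,
  7005,
  7006,
  7007,
  7008,
  7009,
  7010
 ],
 "n_per_class": 8
}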