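{
 "across": 0.1738526283896998,
 "n_across": 516,
 "n_within_medication": 60,
 "n_within_side_effect": 172,
 "within_medication": 0.20412641453266578,
 "within_side_effect": 0.33310386629991096
}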