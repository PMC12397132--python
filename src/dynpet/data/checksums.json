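{
 "reference_kinetic_params.csv": "e0bd3f62a902eb5c442d4fe205cc53069943213e9cf4d6f5baf10946cb2f45f8",
 "reference_bias_2iter.csv": "eedc65bf3834b3762d19057e1d9d640482cd13b4fd662fa985dee49fc642485d",
 "reference_bias_6iter.csv": "25b14681c50b95c1babe7415b547ca1e1f1a7338023db13d2e58ff932d05c4ae"
}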