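{
 "alpha7_Ftex": 0.166,
 "gamma7": 0.118,
 "gamma6": 0.0142,
 "alpha9": 0.283,
 "gamma9": 0.00031,
 "K47": 0.11,
 "alpha1_Feex_x2": 0.00015,
 "alpha6_x3_eff": 0.0019,
 "alpha10": null,
 "alpha11": 1.0,
 "alpha2": 0.01,
 "gamma2": 0.01,
 "alpha3": 0.01,
 "gamma3": 0.008,
 "gammah_Hep": 0.002,
 "alpha4_storage": 0.0008,
 "gamma4": 0.0001,
 "alpha5": 0.01,
 "gamma5": 0.01,
 "k15": 1.0,
 "k52": 1.0,
 "k53": 1.0,
 "k54": 1.0,
 "frozen_core": true,
 "literal_processing": false
}
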