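onset_fraction,offset_fraction,sigma_star,cv
0.14823059679227418,0.08962977475681401,0.043522722655194204,0.015197237599680917
0.12276662291739183,0.08962977475681401,0.03739949553102456,0.010182231260617496
0.14823059679227418,0.07805835345636808,0.03659810146283443,0.015395370171474534
0.12276662291739183,0.07805835345636808,0.05092349048236202,0.013286574813794165
0.135498609854833,0.08384406410659104,0.03301979835921065,0.009558145056861311
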