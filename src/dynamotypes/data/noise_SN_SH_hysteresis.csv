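onset_fraction,offset_fraction,sigma_star,cv
0.6883402264026532,0.39277052061462736,0.0058056069616012765,0.05119230573064535
0.6207256931935304,0.39277052061462736,0.004829326168298953,0.0539810839571287
0.6883402264026532,0.5621507410660251,0.0037644703732809003,0.05032672112305994
0.6207256931935304,0.5621507410660251,0.01099916350798386,0.0724249867343379
0.6545329597980918,0.4774606308403262,0.006611359225735862,0.05600346564432177
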