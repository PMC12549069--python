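onset_fraction,offset_fraction,sigma_star,cv
0.08350717188231867,0.32510723444897915,0.06675872077782713,0.02223768236441186
0.05797611311939958,0.32510723444897915,0.07124092803952263,0.02224143372616915
0.08350717188231867,0.6750812646769813,0.07280090123106128,0.023062978805712894
0.05797611311939958,0.6750812646769813,0.07685192036487298,0.021324161607027086
0.07074164250085913,0.5000942495629802,0.07399325731722478,0.019908176582005287
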