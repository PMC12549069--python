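onset_fraction,offset_fraction,sigma_star,cv
0.05148577640197777,0.7293076302743751,0.0039311377155419845,0.02034488769828975
0.09066783886581414,0.7293076302743751,0.003378064570753783,0.01423108044699995
0.05148577640197777,0.7687598919592866,0.0036244432627159017,0.010153324188488716
0.09066783886581414,0.7687598919592866,0.004881914082382523,0.018097068907093776
0.07107680763389596,0.7490337611168308,0.003909907305512825,0.012217750950333683
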