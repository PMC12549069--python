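onset_fraction,offset_fraction,sigma_star,cv
0.14944337245857411,0.22628836347891512,0.043053896460990185,0.02974586169713714
0.12963901835975816,0.22628836347891512,0.09805857594353394,0.04780080364544612
0.14944337245857411,0.20648799205489946,0.043053896460990185,0.019431743054149544
0.12963901835975816,0.20648799205489946,0.0985910243141696,0.034105652002427
0.13954119540916615,0.21638817776690727,0.09188910464015909,0.06437771669015545
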