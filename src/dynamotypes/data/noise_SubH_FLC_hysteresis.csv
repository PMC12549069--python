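onset_fraction,offset_fraction,sigma_star,cv
0.02301542462948833,0.03668069834042429,0.004380807753518691,0.007918653253316041
0.04473270163546887,0.03668069834042429,0.00549958175399193,0.0051415731472606516
0.02301542462948833,0.0466858296423279,0.002934412938254948,0.005169524265135861
0.04473270163546887,0.0466858296423279,0.0048032450228045614,0.010178083517684811
0.0338740631324786,0.04168326399137609,0.005381737057623773,0.00865593418321409
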