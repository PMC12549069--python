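onset_fraction,offset_fraction,sigma_star,cv
0.6608834771237214,0.7507414597639697,0.056137168988998495,0.00852681832371525
0.6158803844972484,0.7507414597639697,0.06188463736968098,0.007922684576252984
0.6608834771237214,0.7141555180118051,0.0625585168882052,0.08588649285400153
0.6158803844972484,0.7141555180118051,0.055532460145321434,0.005261421218701068
0.6383819308104849,0.7324484888878874,0.05346681766028359,0.005523761456211147
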