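onset_fraction,offset_fraction,sigma_star,cv
0.672091768000825,0.5376141303157834,0.13644109282131575,0.050679154859911694
0.6246557476838278,0.5376141303157834,0.23962496403112965,0.05840537960441816
0.672091768000825,0.7125824815946527,0.14248185607904526,0.05088966183508385
0.6246557476838278,0.7125824815946527,0.16491420999160364,0.05231549409189709
0.6483737578423264,0.625098305955218,0.15622125063624073,0.05361808827633063
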