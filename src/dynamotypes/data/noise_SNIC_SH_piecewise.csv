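onset_fraction,offset_fraction,sigma_star,cv
0.5376141303157834,0.2696758839265375,0.08025444556623632,0.05239867615489655
0.7125824815946527,0.2696758839265375,0.08564276119764974,0.04281321628675417
0.5376141303157834,0.4218518498141725,0.08380761342806858,0.04578961876703332
0.7125824815946527,0.4218518498141725,0.08156887814872407,0.042871280565858975
0.625098305955218,0.34576386687035504,0.08025444556623632,0.05265783136063833
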