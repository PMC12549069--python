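onset_fraction,offset_fraction,sigma_star,cv
0.07501813682768958,0.15328988107300584,0.2048,0.05279431149848031
0.4251027753569076,0.15328988107300584,0.1040771394468816,0.03268345658247573
0.07501813682768958,0.11363295535885948,0.06055857720239827,0.011783656609675572
0.4251027753569076,0.11363295535885948,0.20591204374790203,0.050892229576966465
0.2500604560922986,0.13346141821593266,0.10020577915778049,0.022166699586978603
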