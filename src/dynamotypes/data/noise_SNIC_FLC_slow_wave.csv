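onset_fraction,offset_fraction,sigma_star,cv
0.5751027753569076,0.03668069834042429,0.1063561320408452,0.0521228472470216
0.9250181368276895,0.03668069834042429,0.1231008493007568,0.053244211421385856
0.5751027753569076,0.0466858296423279,0.0520385697234408,0.02439062620819381
0.9250181368276895,0.0466858296423279,0.10521046518976142,0.04414830590675544
0.7500604560922985,0.04168326399137609,0.10351506289169414,0.04317284725146708
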