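onset_fraction,offset_fraction,sigma_star,cv
0.599925897564406,0.08350717188231867,0.18678818666568228,0.0506636579993593
0.5610311730426905,0.08350717188231867,0.17315069944517686,0.05093167967871647
0.599925897564406,0.05797611311939958,0.20369396192944808,0.05017660664148537
0.5610311730426905,0.05797611311939958,0.17598661612774175,0.054175392579611195
0.5804785353035482,0.07074164250085913,0.17315069944517686,0.050420653773001235
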