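onset_fraction,offset_fraction,sigma_star,cv
0.40957419933878275,0.010329417718303936,0.006611359225735862,0.011323313664353903
0.3872225798005531,0.010329417718303936,0.0076938030812973,0.009678712209036577
0.40957419933878275,0.015816006788355444,0.005323765057045557,0.009188398206220243
0.3872225798005531,0.015816006788355444,0.0070552485331701826,0.010736070183531678
0.3983983895696679,0.01307271225332969,0.00501590284788977,0.0029904068208561193
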