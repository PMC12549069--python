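onset_fraction,offset_fraction,sigma_star,cv
0.08350717188231867,0.37449453481932926,0.07520514218685347,0.015889423826482677
0.05797611311939958,0.37449453481932926,0.0985910243141696,0.01504274822365418
0.08350717188231867,0.45858682155933594,0.07520514218685347,0.01668253236130878
0.05797611311939958,0.45858682155933594,0.2743639089261165,0.06698298893061512
0.07074164250085913,0.4165406781893326,0.07726921869278325,0.01594572285024118
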