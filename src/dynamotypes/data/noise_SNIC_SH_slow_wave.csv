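onset_fraction,offset_fraction,sigma_star,cv
0.5376141303157834,0.37449453481932926,0.02518747165738465,0.019697947861103945
0.7125824815946527,0.37449453481932926,0.02616056700554539,0.024365602175494543
0.5376141303157834,0.45858682155933594,0.0653282190538953,0.0434782647000921
0.7125824815946527,0.45858682155933594,0.06748567558482249,0.0372540792689699
0.625098305955218,0.4165406781893326,0.035620464019761315,0.026631856166787746
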