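onset_fraction,offset_fraction,sigma_star,cv
0.03751691991001824,0.787564344766963,0.013883115036330359,0.018420599694627796
0.21259587949010336,0.787564344766963,0.0246477560785424,0.029874578689005834
0.03751691991001824,0.9625113549588759,0.0246477560785424,0.013581949494608536
0.21259587949010336,0.9625113549588759,0.016509899179605325,0.017610384987440737
0.1250563997000608,0.8750378498629194,0.014034292247249624,0.016611432755100387
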