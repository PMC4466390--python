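label,kd_uM,kd_se_uM,measure,ph
PDZ1 (1-140),1.7,0.2,KD_EC50,7.4
PDZ1 (1-140) pH 5.5,16.1,3.3,KD_EC50,5.5
PDZ1 (1-140) pH 6.0,8.0,1.8,KD_EC50,6.0
PDZ1 (11-120),5.5,0.6,KD_EC50,7.4
PDZ2 D183E,20.0,10.0,KD_EC50,7.4
PDZ2 N167H/D183E,11.7,2.0,KD_EC50,7.4
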