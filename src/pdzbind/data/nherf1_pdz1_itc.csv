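label,kd_uM,dH_kcal_mol,dS_cal_mol_K,dG_kcal_mol,T_K,n
WT,3.1,-8.2,-2.1,-7.6,298.15,0.92
H27N,5.3,-7.5,-0.86,-7.2,298.15,0.61
E43D,10.4,-3.0,12.7,-6.8,298.15,0.60
H27N/E43D,17.9,-5.8,2.3,-6.5,298.15,0.60
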