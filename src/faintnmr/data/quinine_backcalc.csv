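sample_id,prepared_mM,backcalc_mM,backcalc_sigma_mM,backcalc_lin_mM,backcalc_lin_sigma_mM
1,5.29,5.35,0.10,5.63,0.02
2,29.44,28.43,0.58,30.05,0.05
3,48.19,48.10,0.98,50.84,0.06
4,77.78,75.14,0.53,81.05,0.13
5,108.35,100.42,0.75,108.30,0.15
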