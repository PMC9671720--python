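sample_id,target_mM,weight_mg,molecular_weight,volume_ml,concentration_mM,n_rg_values,highest_rg
1,5,1.03,324.42,0.6,5.29,17,161
2,30,5.73,324.42,0.6,29.44,12,90.5
3,50,9.38,324.42,0.6,48.19,12,90.5
4,80,15.14,324.42,0.6,77.78,5,40.3
5,110,21.09,324.42,0.6,108.35,4,36
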