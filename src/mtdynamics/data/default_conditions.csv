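label,k_a_dimers_per_uM_s,k_d_dimers_per_s,f_cat_per_min,v_shrink_um_min,hill_C_uM,hill_s,spont_slope_per_field_uM,spont_Cc_uM,v_depoly_gmpcpp_um_min,f_rescue_per_min
control,2.6,7.514,0.3,10.0,6.85,3.37,2.0,25.4,0.013,0.0
ckap2_125nM,109.2,2.5,0.05,10.0,0.18,6.96,0.0,0.0,0.0,0.0
ckap2_200nM,120.0,2.8,0.04,10.0,0.10,3.5,30.0,0.25,0.0,0.0
ckap2_500nM,142.0,2.84,0.02,10.0,0.05,3.10,0.0,0.0,0.0,0.0
ckap2_1uM,142.0,2.84,0.01,10.0,0.05,3.79,0.0,0.0,0.0,0.0
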