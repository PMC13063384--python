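round,n_experts,n_items,w,df,mean_cv,chi2,p_label
1,17,76,0.471,75,0.16,600.13,<0.001
2,16,67,0.348,66,0.12,367.92,<0.001
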