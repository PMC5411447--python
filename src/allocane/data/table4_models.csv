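crop,source_label,provenance,predictor,coefficient_a,ln_coefficient_a,exponent_b,r_squared,rms,aic,aicc
napiergrass,site_specific_D,site_specific,D,151.26,,0.68,0.98,27,134,135
napiergrass,site_specific_H,site_specific,H,47.98,,0.35,0.93,47,136,137
napiergrass,generalized_lnD,generalized,logD_exp_form,,-2.134,2.530,0.55,702,199,200
napiergrass,generalized_H,generalized,H,5.37e-5,,2.714,0.89,476,185,186
napiergrass,generalized_DH,generalized,D_times_H,0.0612,,1.5811,0.89,316,171,177
energycane,site_specific_D,site_specific,D,144.99,,0.72,0.96,18,89,90
energycane,site_specific_H,site_specific,H,48.90,,0.36,0.91,19,91,92
energycane,generalized_lnD,generalized,logD_exp_form,,-2.134,2.530,0.88,28,102,103
energycane,generalized_H,generalized,H,5.37e-5,,2.714,0.75,149,154,155
energycane,generalized_DH,generalized,D_times_H,0.0612,,1.5811,0.72,1110,212,213
sugarcane,site_specific_D,site_specific,D,309.34,,0.71,0.97,491,187,188
sugarcane,site_specific_H,site_specific,H,16.08,,0.73,0.94,895,205,206
sugarcane,generalized_lnD,generalized,logD_exp_form,,-2.134,2.530,0.68,47200,325,326
sugarcane,generalized_H,generalized,H,5.37e-5,,2.714,0.78,1950,295,296
sugarcane,generalized_DH,generalized,D_times_H,0.0612,,1.5811,0.87,4920,256,257
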