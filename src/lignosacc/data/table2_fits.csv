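sample_id,biomass,pretreatment,yield_48h_pct,yield_48h_sd,ci_pct,ci_sd,cf_pct,r_ca_cellu
sigmacell,Sigmacell,NA,86.6,3.8,22.0,0.8,22.0,0.20
avicel,AVICEL,NA,86.6,1.1,53.0,2.0,55.0,0.60
avicel_lignin,AVICEL and Organosolv Lignin,NA,72.8,3.3,53.0,2.0,55.0,0.40
beech_untreated,Beech,untreated,9.5,0.2,21.0,0.8,22.0,0.005
beech_ns_ocat,Beech,NS+OCAT,50.8,0.4,43.0,1.6,45.0,0.04
beech_ys_ocat,Beech,YS+OCAT,40.9,0.6,51.0,1.9,45.0,0.05
miscanthus_untreated,Miscanthus,untreated,11.5,0.6,29.0,0.8,31.0,0.05
miscanthus_ns_ocat,Miscanthus,NS+OCAT,81.9,0.3,45.0,1.7,43.0,0.30
miscanthus_ys_ocat,Miscanthus,YS+OCAT,47.0,4.4,30.0,1.1,33.0,0.001
sida_untreated,Sida,untreated,12.4,0.5,23.0,0.9,22.0,0.05
sida_ns_ocat,Sida,NS+OCAT,87.5,4.3,38.0,1.4,37.0,0.50
sida_ys_ocat,Sida,YS+OCAT,40.4,1.4,34.0,1.3,36.0,0.001
walnut_untreated,Walnut,untreated,3.0,0.2,26.0,1.0,29.0,0.0001
walnut_ns_ocat,Walnut,NS+OCAT,41.0,2.5,37.0,1.4,37.0,0.01
walnut_ys_ocat,Walnut,YS+OCAT,22.6,1.0,47.0,1.7,45.0,0.0001
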