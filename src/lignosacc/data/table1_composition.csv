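sample_id,biomass,pretreatment,cellulose_pct,cellulose_sd,lignin_pct,lignin_sd,mps_pct,mps_sd,acetate_pct,acetate_sd,total_pct,lignin_artifact
avicel,AVICEL,NA,80.6,0.78,11.3,0.75,3.7,0.17,3.9,0.09,99.5,1
sigmacell,Sigmacell,NA,82.8,0.82,9.2,0.68,4.0,0.18,3.6,0.13,99.2,1
beech_untreated,Beech,untreated,45.3,1.7,24.7,2.0,22.8,3.5,5.1,0.5,97.9,0
beech_ns_ocat,Beech,NS+OCAT,71.0,1.5,21.8,1.0,4.2,0.5,0.0,0.1,97.1,0
beech_ys_ocat,Beech,YS+OCAT,68.6,1.5,23.8,2.5,1.9,0.1,0.0,0.0,94.3,0
miscanthus_untreated,Miscanthus,untreated,46.5,4.3,24.4,2.2,24.3,3.6,2.7,0.1,97.8,0
miscanthus_ns_ocat,Miscanthus,NS+OCAT,71.9,2.0,20.9,1.1,5.9,0.8,0.0,0.0,98.7,0
miscanthus_ys_ocat,Miscanthus,YS+OCAT,80.8,2.7,19.7,1.1,1.8,0.1,0.1,0.1,102.4,0
sida_untreated,Sida,untreated,44.7,2.3,25.2,1.2,17.6,2.5,5.1,0.2,92.6,0
sida_ns_ocat,Sida,NS+OCAT,62.1,0.9,18.2,1.5,6.6,0.7,0.1,0.2,87.1,0
sida_ys_ocat,Sida,YS+OCAT,68.5,0.8,23.7,0.5,3.4,0.5,0.4,0.1,96.0,0
walnut_untreated,Walnut,untreated,31.4,4.0,28.4,1.9,15.7,3.2,4.6,0.2,80.2,0
walnut_ns_ocat,Walnut,NS+OCAT,50.9,1.8,28.4,2.5,6.8,0.1,0.2,0.1,86.3,0
walnut_ys_ocat,Walnut,YS+OCAT,50.0,1.0,29.3,0.3,3.5,0.6,0.2,0.1,83.0,0
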