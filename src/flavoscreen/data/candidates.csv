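id,name,smiles,ic50_pred_um
cand-1,"2-(3,5-dihydroxyphenyl)-5,7-dihydroxy-4H-chromen-4-one",O=c1cc(-c2cc(O)cc(O)c2)oc2cc(O)cc(O)c12,8.98
cand-2,Norartocarpetin,O=c1cc(-c2ccc(O)cc2O)oc2cc(O)cc(O)c12,31.95
cand-3,"2-(2,5-dihydroxyphenyl)-5,7-dihydroxy-4H-chromen-4-one",O=c1cc(-c2cc(O)ccc2O)oc2cc(O)cc(O)c12,78.57
cand-4,"2-(3,4-dihydroxyphenyl)-5-hydroxy-4H-chromen-4-one",O=c1cc(-c2ccc(O)c(O)c2)oc2cccc(O)c12,87.87
cand-5,Morelosin,COc1cc(O)c2c(=O)cc(-c3ccc(O)cc3)oc2c1,94.14
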