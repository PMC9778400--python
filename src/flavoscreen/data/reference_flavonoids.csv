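cid,name,alt_name,smiles,pic50,pic50_pred_2d,residual_2d,pic50_pred_3d,residual_3d
5280443,Apigenin,,O=c1cc(-c2ccc(O)cc2)oc2cc(O)cc(O)c12,3.224,3.684,-0.46,3.593,-0.37
5281605,Baicalein,,O=c1cc(-c2ccccc2)oc2cc(O)c(O)c(O)c12,3.586,3.42,0.166,3.29,0.296
5281616,Galangin,,O=c1c(O)c(-c2ccccc2)oc2cc(O)cc(O)c12,3.381,3.284,0.097,3.122,0.259
5281654,Isorhamnetin,,COc1cc(-c2oc3cc(O)cc(O)c3c(=O)c2O)ccc1O,3.17,3.271,-0.102,3.264,-0.095
5280445,Luteolin,,O=c1cc(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12,4.082,3.938,0.144,4.054,0.028
5281672,Myricetin,,O=c1c(O)c(-c2cc(O)c(O)c(O)c2)oc2cc(O)cc(O)c12,4.934,4.92,0.014,4.729,0.206
5280863,Kaempferol,,O=c1c(O)c(-c2ccc(O)cc2)oc2cc(O)cc(O)c12,3.814,3.751,0.064,3.746,0.068
5280343,Quercetin,,O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)cc(O)c12,3.939,4.05,-0.111,4.008,-0.07
5280704,Apigenin-7-O-glucoside,Cosmosiin,OCC1OC(Oc2cc(O)c3c(=O)cc(-c4ccc(O)cc4)oc3c2)C(O)C(O)C1O,4.642,3.468,1.174,3.502,1.14
72281,Hesperitin,Hesperetin,COc1ccc(C2CC(=O)c3c(O)cc(O)cc3O2)cc1O,2.72,2.654,0.067,2.708,0.012
5280441,Vitexin,,O=c1cc(-c2ccc(O)cc2)oc2c(C3OC(CO)C(O)C(O)C3O)c(O)cc(O)c12,3.448,3.353,0.095,3.302,0.147
5281614,Fisetin,,O=c1c(O)c(-c2ccc(O)c(O)c2)oc2cc(O)ccc12,4.334,3.839,0.494,4.271,0.063
439533,Taxifolin,,O=C1c2c(O)cc(O)cc2OC(c2ccc(O)c(O)c2)C1O,2.531,2.371,0.16,2.869,-0.338
440735,Eriodictyol,,O=C1CC(c2ccc(O)c(O)c2)Oc2cc(O)cc(O)c21,2.986,2.911,0.075,3.035,-0.049
4788,Phloretin,,O=C(CCc1ccc(O)cc1)c1c(O)cc(O)cc1O,3.85,3.806,0.045,3.865,-0.015
9064,(+)-Catechin,,OC1Cc2c(O)cc(O)cc2OC1c1ccc(O)c(O)c1,1.789,1.888,-0.098,1.729,0.06
5280637,Luteoloside,Luteolin-7-O-glucoside,OCC1OC(Oc2cc(O)c3c(=O)cc(-c4ccc(O)c(O)c4)oc3c2)C(O)C(O)C1O,3.365,3.582,-0.217,3.463,-0.098
5280378,Formononetin,,COc1ccc(-c2coc3cc(O)ccc3c2=O)cc1,3.126,3.189,-0.063,3.101,0.025
5280961,Genistein,,O=c1c(-c2ccc(O)cc2)coc2cc(O)cc(O)c12,3.192,3.219,-0.027,3.357,-0.164
172648475,Kaempferol-7-O-b-glucoside,,OCC1OC(Oc2cc(O)c3c(=O)c(O)c(-c4ccc(O)cc4)oc3c2)C(O)C(O)C1O,3.689,3.47,0.219,3.654,0.035
5281673,Myricetin,Myricitrin,CC1OC(Oc2c(-c3cc(O)c(O)c(O)c3)oc3cc(O)cc(O)c3c2=O)C(O)C(O)C1O,3.51,2.776,0.734,4.997,-1.487
441667,Cyanidin-3-O-glucoside,,OCC1OC(Oc2cc3c(O)cc(O)cc3[o+]c2-c2ccc(O)c(O)c2)C(O)C(O)C1O,4.197,4.204,-0.006,4.365,-0.168
65064,Epigallocatechin Gallate,,O=C(OC1Cc2c(O)cc(O)cc2OC1c1cc(O)c(O)c(O)c1)c1cc(O)c(O)c(O)c1,4.011,4.009,0.002,3.826,0.185
3084995,Isoschaftoside,,O=c1cc(-c2ccc(O)cc2)oc2c(C3OC(CO)C(O)C(O)C3O)c(O)c(C3OCC(O)C(O)C3O)c(O)c12,3.411,3.646,-0.234,3.366,0.045
5280805,Rutin,,CC1OC(OCC2OC(Oc3c(-c4ccc(O)c(O)c4)oc4cc(O)cc(O)c4c3=O)C(O)C(O)C2O)C(O)C(O)C1O,3.761,3.623,0.138,3.771,-0.01
56776173,Vitexin-4'-O-glucoside,,OCC1OC(Oc2ccc(-c3cc(=O)c4c(O)cc(O)c(C5OC(CO)C(O)C(O)C5O)c4o3)cc2)C(O)C(O)C1O,3.354,3.049,0.306,2.898,0.456
5481663,Isorhamnetin-3-O-rutinoside,,COc1cc(-c2oc3cc(O)cc(O)c3c(=O)c2OC2OC(COC3OC(C)C(O)C(O)C3O)C(O)C(O)C2O)ccc1O,3.268,3.245,0.023,3.196,0.072
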