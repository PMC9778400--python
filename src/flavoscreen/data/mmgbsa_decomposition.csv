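complex,e_vdw,e_ele,g_pol,g_nonpol,g_gas,g_sol,g_bind
"2-(3,5-dihydroxyphenyl)-5,7-dihydroxy-4H-chromen-4-one",-23.24 ± 1.95,-38.62 ± 5.45,41.82 ± 3.12,-3.84 ± 0.27,-61.86 ± 5.44,37.98 ± 3.01,-23.87 ± 3.18
Norartocarpetin,-30.29 ± 2.98,-53.66 ± 5.59,51.32 ± 3.38,-5.15 ± 0.13,83.95 ± 4.93,46.17 ± 3.36,-37.78 ± 3.28
"2-(2,5-dihydroxyphenyl)-5,7-dihydroxy-4H-chromen-4-one",-26.31 ± 4.52,-46.07 ± 9.18,48.7 ± 8.00,-4.13 ± 0.34,-72.38 ± 10.14,44.57 ± 7.72,-27.81 ± 3.45
"2-(3,4-dihydroxyphenyl)-5-hydroxy-4H-chromen-4-one",-35.28 ± 2.77,-15.2 ± 10.68,32.38 ± 7.23,-4.43 ± 0.15,-50.48 ± 9.98,27.95 ± 7.25,-22.53 ± 3.40
Morelosin,-29.34 ± 2.45,-7.1 ± 3.49,23.99 ± 3.64,-4.11 ± 0.23,-36.43 ± 4.19,19.88 ± 3.52,-16.56 ± 2.55
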