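drug,atc_code,n11,n10,nplus1,nplusplus,ror,ci_low,ci_high,ic,ic025
Nirmatrelvir/ritonavir,J05AE30,3968,72107,24485,10177264,27.04,26.11,27.99,4.43,4.38
Sunitinib malate,L01XJ01,514,28585,24485,10177264,7.59,6.95,8.29,2.86,2.73
Clarithromycin,J01FA09,419,14487,24485,10177264,12.18,11.05,13.44,3.51,3.37
Enzalutamide,L02BB04,358,51749,24485,10177264,2.90,2.61,3.22,1.51,1.35
Palbociclib,L01EF01,259,67521,24485,10177264,1.60,1.41,1.81,0.66,0.48
Pazopanib hydrochloride,L01EX03,155,18404,24485,10177264,3.51,2.99,4.11,1.77,1.54
Terbinafine hydrochloride,D01AE15,104,1645,24485,10177264,26.32,21.58,32.10,4.33,4.04
Crizotinib,L01ED01,76,8697,24485,10177264,3.63,2.90,4.55,1.80,1.47
Fluorouracil,L01BC02,57,12833,24485,10177264,1.84,1.42,2.39,0.86,0.48
Varenicline tartrate,N07BA03,52,9353,24485,10177264,2.31,1.76,3.03,1.17,0.77
Enfortumab vedotin,L01FX13,39,1983,24485,10177264,8.17,5.95,11.21,2.77,2.31
Panitumumab,L01FE02,33,7525,24485,10177264,1.82,1.29,2.56,0.83,0.33
Romidepsin,L01XH02,10,1139,24485,10177264,3.64,1.95,6.79,1.55,0.67
Vorinostat,L01XH01,8,550,24485,10177264,6.03,3.00,12.13,1.94,0.97
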