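treatment,n_supply,genotype,anue,npfp
N130a,130,Meseta,20.12,46.93
N130a,130,Jallon,13.89,46.69
N130a,130,Smooth,22.38,57.06
N130b,130,Meseta,21.69,48.51
N130b,130,Jallon,19.13,51.94
N130b,130,Smooth,20.91,55.58
N150a,150,Meseta,18.09,41.34
N150a,150,Jallon,16.67,45.10
N150a,150,Smooth,17.65,47.69
N150b,150,Meseta,17.75,40.99
N150b,150,Jallon,20.44,48.87
N150b,150,Smooth,20.05,50.10
N150c,150,Meseta,20.89,44.13
N150c,150,Jallon,21.11,49.54
N150c,150,Smooth,23.00,53.05
N170a,170,Meseta,17.84,38.35
N170a,170,Jallon,11.97,37.06
N170a,170,Smooth,18.24,44.75
N170b,170,Meseta,18.90,39.41
N170b,170,Jallon,15.50,40.58
N170b,170,Smooth,16.80,43.31
N170c,170,Meseta,19.51,40.01
N170c,170,Jallon,17.96,43.04
N170c,170,Smooth,19.43,45.94
N170d,170,Meseta,17.28,37.78
N170d,170,Jallon,18.61,43.69
N170d,170,Smooth,23.45,49.96
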