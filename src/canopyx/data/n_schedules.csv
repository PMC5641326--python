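treatment,n_supply,presowing,emergence,tillering,booting
N0,0,0,0,0,0
N130a,130,0,65,0,65
N130b,130,40,50,0,40
N150a,150,0,65,0,85
N150b,150,40,0,110,0
N150c,150,40,50,0,60
N170a,170,0,65,0,105
N170b,170,0,85,0,85
N170c,170,40,0,130,0
N170d,170,40,50,0,80
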