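name,smiles
Guanidine,NC(=N)N
Tryptophan,NC(Cc1c[nH]c2ccccc12)C(=O)O
Methylamine,CN
sec-Butylamine,CCC(C)N
n-Octylamine,CCCCCCCCN
Morpholine,C1COCCN1
Procaine,CCN(CC)CCOC(=O)c1ccc(N)cc1
Dimethyl-iso-propylamine,CC(C)N(C)C
p-Toluidine,Cc1ccc(N)cc1
Nikethamide,CCN(CC)C(=O)c1cccnc1
nicotine,CN1CCCC1c1cccnc1
lidocaine,CCN(CC)CC(=O)Nc1c(C)cccc1C
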