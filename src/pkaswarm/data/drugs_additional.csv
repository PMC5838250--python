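name,pka_exp
Guanidine,13.8
Clomipramine,9.42
Papaverine,6.4
Clotrimazole,5.75
Tryptophan,9.1
Methylamine,10.62
sec-Butylamine,10.56
Imipramine,9.6
n-Octylamine,10.7
Morpholine,8.5
Procaine,9.11
Guanethidine,11.4
"Imidazo[2,3-b]thioxazole",8
Trimipramine,9.39
Dimethyl-iso-propylamine,10.3
tert-Butylcyclohexylamine,11.23
Sotalol,9.3
Alphaprodine,8.7
p-Toluidine,5.1
Nikethamide,3.5
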