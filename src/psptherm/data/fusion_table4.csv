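name,Tm_K,dHm_J_mol
Carvedilol,388.15,47360
Cyclosporine A,,
Ketoconazole,422.29,53160
Loratadine,407.29,27970
Simvastatin,412.21,29160
Zafirlukast,467.95,19600
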