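# Synthetic probe-property table: nominal literature-magnitude physical
# properties of common IGC probe gases at a 303.15 K column temperature.
# These values are editable stand-ins (the primary data source prints none);
# override any column for quantitative work.
# p0_Pa: saturation vapor pressure; B11_m3_mol: second virial coefficient;
# V1_m3_mol: liquid molar volume; M_kg_mol: molar mass.
name,M_kg_mol,p0_Pa,B11_m3_mol,V1_m3_mol
n-Heptane,0.100204,7780,-0.00260,0.000147
n-Octane,0.114229,2470,-0.00370,0.000164
n-Nonane,0.128257,810,-0.00500,0.000180
n-Decane,0.142285,260,-0.00700,0.000196
Acetone,0.058080,37990,-0.00190,0.0000740
Acetonitrile,0.041053,15060,-0.00530,0.0000530
Ethyl acetate,0.088106,15950,-0.00250,0.0000985
Dichloromethane,0.084933,70650,-0.00090,0.0000640
Methanol,0.032042,21870,-0.00190,0.0000407
Ethanol,0.046068,10450,-0.00260,0.0000587
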