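name,Vx,E,S,A,B,M,gamma_d_mJ_m2,sigma_d_MPa05,Tm_K,dHm_J_mol
Carvedilol,3.10,3.08,3.19,0.50,1.45,0.40648,47.83,19.75,388.15,47360
Cyclosporine A,10.02,4.23,7.72,0.70,4.50,1.20261,13.19,18.04,,
Ketoconazole,3.72,3.14,2.75,0.00,0.70,0.53143,45.86,19.52,422.29,53160
Loratadine,2.87,2.19,2.96,0.00,0.60,0.38288,41.60,19.11,407.29,27970
Simvastatin,3.43,1.35,4.28,0.20,0.70,0.41857,57.36,17.82,412.21,29160
Zafirlukast,4.23,3.64,4.66,0.71,2.10,0.57568,49.43,19.60,467.95,19600
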