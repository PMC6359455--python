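name,Vx,E,S,A,B
n-Hexane,0.954,,,,
n-Heptane,1.095,,,,
n-Octane,1.236,,,,
n-Nonane,1.377,,,,
n-Decane,1.518,,,,
Cyclohexane,0.845,0.310,0.010,,
Carbon tetrachloride,0.739,0.460,0.380,,
Benzene,0.716,0.610,0.520,,
Toluene,0.857,0.600,0.520,,
Ethylbenzene,0.998,0.610,0.510,,
Acetone,0.547,0.180,0.703,,0.493
Methyl ethyl ketone,0.688,0.170,0.697,,0.510
Ethyl acetate,0.747,0.110,0.618,,0.450
n-Butyl acetate,1.028,0.071,0.597,,0.449
Tetrahydrofuran,0.622,0.291,0.524,,0.479
"1,4-Dioxane",0.681,0.330,0.744,,0.635
Chloroform,0.617,0.430,0.490,0.150,
Dichloromethane,0.494,0.390,0.574,0.100,
Methanol,0.308,0.280,0.439,0.430,0.470
Ethanol,0.449,0.250,0.419,0.370,0.480
1-Propanol,0.590,0.240,0.420,0.370,0.480
1-Butanol,0.731,0.220,0.420,0.370,0.480
1-Octanol,1.295,0.200,0.421,0.370,0.480
Isopropanol,0.590,0.210,0.366,0.330,0.560
2-Butanol,0.731,0.220,0.360,0.330,0.560
Cyclohexanol,0.904,0.461,0.557,0.320,0.570
Phenol,0.775,0.808,0.890,0.600,0.300
Ethylene glycol,0.508,0.400,0.900,0.580,0.780
Acetonitrile,0.404,0.241,0.900,0.040,0.330
Water,0.167,0.000,0.450,0.820,0.350
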