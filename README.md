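# psptherm

Partial solvation parameters (PSP) for pharmaceutics: a thermodynamic
toolkit that turns Abraham-type LSER descriptors of drugs and solvents into
solubility-parameter components, hydrogen-bonding association equilibria,
activity coefficients, drug solubilities, acid/base surface-energy
components, and infinite-dilution activity coefficients reduced from
inverse gas chromatography (IGC) — plus estimation of a drug's descriptors
from probe-gas measurements.

It is aimed at formulation scientists screening solvents and excipients for
poorly water-soluble drugs, and at anyone reducing IGC retention data on
drug stationary phases to thermodynamic quantities.

## The model

A compound is characterized by its McGowan volume *V*<sub>x</sub> (in
(cm³/mol)/100), excess refractivity *E*, polarity *S*, hydrogen-bond
acidity *A* and basicity *B*. With the molar volume *V*<sub>m</sub>
(cm³/mol), the partial solvation parameters (MPa<sup>0.5</sup>) are

```
σ_d  = 100 √((3.1·Vx + E)/Vm)      σ_p  = 100 √(S/Vm)
σ_Ga = 100 √(A/Vm)                 σ_Gb = 100 √(B/Vm)
```

A donor–acceptor hydrogen bond between species *i* and *j* forms with
Gibbs energy *G*<sub>HB</sub> = −(30450 − 35.1 *T*)·√(*A*<sub>i</sub>*B*<sub>j</sub>)
J/mol; the equilibrium reduced bond numbers ν<sub>ij</sub> follow
Veytsman's statistics,

```
ν_ij / (ν_i0 ν_0j) = exp(−G_HB,ij / RT)
```

subject to donor/acceptor balances, which psptherm solves by exact
per-pair coordinate updates with a Newton polish. The solute activity
coefficient splits into a Flory–Huggins combinatorial part (segment number
*r* = *V*<sub>x</sub>/0.213) and residual dispersion (VE), polarity (S) and
hydrogen-bonding (H) parts; the residual sum defines the interaction
parameter through ln γ₁<sup>res</sup> = *r*₁χ₁₂φ₂². Crystalline-drug
solubility follows the classical solid–liquid equilibrium with the fusion
enthalpy and melting point, and surface energy decomposes into a nonpolar
part γ_VES plus acid/base components proportional to *A* and *B* with
γ_hb = 2√(γ_a γ_b).

The solvent descriptor table, the six studied drugs (carvedilol,
cyclosporine A, ketoconazole, loratadine, simvastatin, zafirlukast), their
fusion data, and their dispersive surface energies ship as bundled CSV
fixtures.

## Worked example

Surface-energy decomposition of carvedilol from its measured dispersive
surface energy (47.83 mJ/m²) and its IGC-fitted descriptors:

```sh
$ psptherm surface --drug Carvedilol
name,gamma_d,gamma_hb,gamma_tot,gamma_a,gamma_b
Carvedilol,47.83,5.13,52.96,1.51,4.37
```

The hydrogen-bonding component contributes 5.13 mJ/m² on top of the
dispersive 47.83, giving a total surface energy of 52.96 mJ/m², split into
an acidic 1.51 and a basic 4.37 mJ/m² component (carvedilol is a stronger
base than acid, A = 0.50 vs B = 1.45).

Predicted solubility of loratadine in ethanol at 298.15 K:

```sh
$ psptherm solubility --drug Loratadine --solvent Ethanol
solvent,y1,ideal_y1,gamma_C,gamma_res
Ethanol,0.066199,0.048625,0.11524,6.3741
```

The ideal (fusion-only) mole-fraction solubility is 0.0486; the small
combinatorial coefficient (γ_C ≈ 0.115, a size effect favoring dissolution
of the large solute) outweighs the unfavorable residual interactions
(γ_res ≈ 6.37), so the predicted real solubility, y₁ ≈ 0.066, is somewhat
above ideal.

The same machinery runs in the other direction: `psptherm igc-reduce`
turns raw retention data into ln γ<sup>∞</sup> per probe, and
`psptherm fit` estimates a drug's E, S, A, B descriptors from such a
table (`psptherm simulate` generates synthetic ones for method studies).

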