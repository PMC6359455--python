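# Methods

## Model overview

psptherm implements the partial-solvation-parameter (PSP) framework: a
thermodynamic layer over Abraham-type LSER descriptors (Vx, E, S, A, B)
that yields cohesive-energy components, mixture activity coefficients,
solid–liquid solubilities, and surface-energy components from one common
set of molecular parameters.

Key assumptions:

* One proton-donor group per molecule when A > 0 and one acceptor group
  when B > 0. Multi-site typing (e.g. distinct OH and NH donors on one
  drug) is not resolved; descriptors are effective whole-molecule values.
* Every printed product of acidity and basicity enters as √(A·B). This is
  forced by internal consistency: the hydrogen-bond free energy at 298 K
  must equal 2·Vm·σ_Ga·σ_Gb = 20000·√(A·B) given the square-root PSP
  definitions, and only this reading reproduces the published acid/base
  surface components.
* Hydrogen-bond energetics are anchored to the lower-alkanol reference
  (E_HB = −23000 J/mol, S_HB = −26.5 J K⁻¹ mol⁻¹), scaled by √(A·B):
  E_HB = −30450·√(AB) J/mol, S_HB = −35.1·√(AB) J/(K·mol), so
  G_HB = −(30450 − 35.1·T)·√(AB).
* The combinatorial activity term is Flory–Huggins with segment numbers
  r = Vx/0.213; the Guggenheim–Staverman surface-fraction alternative is
  deliberately not implemented, so no q/θ bookkeeping exists anywhere.
* Binary mixtures only. The association solver itself is n-species, but
  the activity/solubility layer exposes solute-in-solvent pairs.

## Parameters and units

| quantity | unit | default | note |
|---|---|---|---|
| Vx | (cm³/mol)/100 | — | McGowan convention; matches solvent-table magnitudes |
| Vm | cm³/mol | inverted from σ_d when absent | drugs rarely have measured Vm |
| T (bulk) | K | 298.15 | activity, solubility, PSP conversion |
| T (IGC) | K | 303.15 | the 30 °C column temperature |
| R | J/(mol·K) | 8.314 | |
| solver residual tolerance | — | 1e-10 (achieved ~1e-15) | equilibrium condition per pair |
| solubility fixed-point tolerance | — | 1e-10 on Δy | damping 0.5 |
| fit convergence | — | 1e-8 max descriptor change | outer alternation |

Molar volumes of the six drugs are recovered by inverting the dispersion
PSP, Vm = 10000·(3.1·Vx + E)/σ_d², because the published tables print σ_d
but never Vm; the recovered volumes reproduce the remaining published PSP
columns to the printed precision, which indicates the same convention was
used upstream. An explicitly supplied Vm always takes precedence.

## Association equilibrium solver

Unknowns are the reduced bond numbers ν_ij (per total lattice segment) for
every donor→acceptor pair with A_i·B_j > 0; pairs that cannot form are
excluded from the system rather than carried with G = 0, which would
assert spurious association. The solver performs cyclic per-pair updates,
each the exact closed-form root of the scalar quadratic obtained by
holding all other pairs fixed — equivalently, exact coordinate
minimization of the convex Veytsman free energy, so every iterate is
feasible and the free energy never increases. Because plain coordinate
sweeps have a slow linear tail when several strong pairs compete for the
same donors, the sweep result is polished by a damped Newton solve of the
stationarity system (analytic Jacobian) to machine precision; a bounded
L-BFGS-B minimization of the free energy remains as a fallback, and
failure past it raises an explicit convergence error carrying the last
residual. The solution is deterministic; no randomness enters anywhere in
the equilibrium path.

Degenerate inputs: a mixture with donors but no acceptors (or vice versa)
returns an all-zero bond state; single-species systems reduce exactly to
the closed-form pure-fluid quadratic.

## Infinite dilution

The analytic infinite-dilution residual (used for IGC work and fitting)
evaluates the quadratic VE and S terms at φ₂ = 1 and builds the
hydrogen-bonding term from the solvent's closed-form self-association
fraction and the cross-association constants A_ij = r₂·exp(G_HB,ij/RT).
The printed form of this equation has ambiguous log grouping; the
parenthesization used here, −ln((1 + A_ij − r₂ν₂₂)/A_ij), is fixed by
requiring agreement with the x₁ → 0 limit of the full composition-
dependent model, which the test suite enforces to 1e-5 over random
descriptor draws (and to ~1e-8 in typical cases). The numerical limit at
x₁ = 1e-8 is the fallback authority wherever the two could disagree.

The truncation error of the numerical limit is O(x₁) with a prefactor
that grows with the solute's self-association constant and with the
magnitude of ln γ itself; the consistency tests therefore draw descriptor
densities in the ranges spanned by the bundled tables (E/Vx ≤ 1.3,
S/Vx ≤ 2.8, moderate solute homosolvation) rather than unbounded values
that no real compound attains.

## Solubility

y₁ = exp{ΔH_m/(RT)·(T/T_m − 1)}/(γ_C·γ_res) is solved by damped (0.5)
fixed-point iteration from the ideal value, with activity coefficients
evaluated at the current saturated composition (not at infinite dilution):
the equilibrium expression contains γ at saturation, and for soluble
systems the difference is substantial. y is capped at 1. ΔCp corrections,
solid-phase activity, and solvate/polymorph thermodynamics are out of
scope; the evaluation utility accepts an index exclusion list for systems
with known solvent-mediated form changes instead.

## Surface energy

γ_d from alkane-probe IGC is identified with the nonhydrogen-bonding
component γ_VES. The acid/base proportionality is taken as
γ_a/A = γ_b/B = γ_VES/(3.1·Vx + E + S); the printed equation's typography
is ambiguous here, and this form is the one that reproduces every
published acid/base cell. Contact angles use the geometric-mean work of
adhesion with cos θ clamped to [−1, 1] so complete wetting and dewetting
return 0° and 180° rather than erroring.

## IGC reduction

All library-level equations are SI (Pa, kg/mol, m³/kg, m³/mol), which
makes the argument of every logarithm dimensionless; the CLI converts
from lab units (sccm, mg, mL/g). The James–Martin compressibility
correction is computed from inlet/outlet pressures when not supplied
directly. Probe saturation pressures, second virial coefficients and
liquid molar volumes at 303.15 K are shipped as a synthetic,
user-overridable fixture of nominal literature-magnitude values
(`probe_properties_synthetic.csv`); quantitative work should substitute
measured or Antoine-derived values, and fitted descriptors inherit
probe-property uncertainty.

## Descriptor fitting

Vx comes from structure; E, S, A, B are fitted to probe ln γ∞ data by
bounded trust-region least squares: stage 1 fits (E, S) holding (A, B),
stage 2 fits (A, B) holding (E, S), alternating, with each cycle finished
by a joint four-parameter refinement from the cycle result plus
deterministic multistarts (ties broken by lowest cost, then smallest
parameter sum). The joint step exists because the two blocks are strongly
correlated through the squared loss — pure alternation crawls — and
because the (A, B) surface can hold shallow local minima. The full-panel
objective is non-increasing along the reported trace.

Identifiability: alkanes alone constrain only one combination of E and S
(their VE and S responses are proportional), so stage 1 uses the full
probe panel, where polar and hydrogen-bonding probes separate the two
through their differing E/Vx and S/Vx densities; aromatic probes, when
available, sharpen E further. A drug's acidity is sensed by
acceptor-carrying probes and its basicity by donor-carrying probes;
warnings are emitted when a direction is unconstrained. With drug-sized
Vx and the default ten-probe panel, E is the weakest coordinate and its
standard error is correspondingly large.

Standard errors are linearized (Wald): cov = s²(JᵀJ)⁻¹ with a
finite-difference Jacobian at the solution. s² is the known observation
variance when the caller provides it (synthetic recovery studies,
characterized instruments) and otherwise SSR/(n − p), which with a
ten-probe panel has only six degrees of freedom and correspondingly heavy
tails. Being local, these intervals undercover in the strongly curved,
weakly identified E direction; coverage statements in the test suite are
therefore per coordinate at known noise, which three-sigma normal theory
supports, not joint across all four descriptors.

## Synthetic data generator

`generate_synthetic_igc` emulates one IGC campaign: the default probe
panel is the ten measured probes (four n-alkanes, acetone, acetonitrile,
ethyl acetate, dichloromethane, methanol, ethanol), clean ln γ∞ values
come from the numerical x₁ = 1e-8 route (keeping the generator
independent of the analytic equation the fitter uses), and i.i.d.
Gaussian noise of chosen SD is added by a seeded generator —
bit-identical per seed. Recovery studies use noise SD 0.05 (a realistic
ln-unit repeatability for IGC) and truth descriptors drawn in the ranges
of the studied drugs. What the generator does not emulate: probe-specific
systematic errors (gas-phase association, finite surface coverage,
deviations from infinite dilution), probe-property errors in p₀/B₁₁, or
correlated noise across probes — so passing recovery tests demonstrate
correctness of the estimator under the model, not robustness to the
experimental artifacts a real campaign faces.

## Known limitations

* The published self-association σ_hb values for carvedilol, simvastatin
  and zafirlukast (8.14, 2.89, 9.01 MPa^0.5) are not recoverable from the
  published descriptors; this package computes 8.39, 3.57, 9.09. The
  implied association constants differ by a near-constant factor ≈ 2.3,
  suggesting unrounded descriptors or a different r/T convention upstream.
  The recomputed values are reported as-is (cyclosporine A agrees to
  0.01). All non-hb components match the published tables to ±0.01.
* Drug descriptors fitted from real IGC data cannot be validated here:
  the raw retention data behind the published values were never released,
  so the fitting stack is validated by synthetic recovery instead.
* Experimental solubilities behind the published regression statistics
  are likewise unpublished; `evaluate_predictions` is provided as the
  generic utility and is validated on synthetic data.
* Binary mixtures; one donor/acceptor type per molecule; no temperature
  dependence of surface tension; no Dorris–Gray extraction of γ_d (it is
  an input).
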