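"""Activity coefficients of binary mixtures in the PSP framework.

ln gamma_1 = ln gamma_1^C (Flory--Huggins combinatorial)
           + ln gamma_1^VE + ln gamma_1^S (quadratic cohesive-density terms)
           + ln gamma_1^H (Veytsman hydrogen-bonding term).

The residual part defines the Flory--Huggins interaction parameter through
ln gamma_1^res = r1 * chi12 * phi2^2.  The infinite-dilution limit has a
closed analytic form used for inverse-gas-chromatography work, where the
probe (solute, index 1) is infinitely dilute in the drug (solvent, index 2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .constants import DISPERSION_VX_COEFF, PSP_SCALE_SQ, R, T_REF
from .descriptors import LSERDescriptors
from .exceptions import DomainError
from .hbond import pair_energy, pure_bond_fraction, solve_equilibrium

__all__ = [
    "MixtureComposition",
    "ActivityBreakdown",
    "combinatorial",
    "ve_contribution",
    "s_contribution",
    "hb_contribution",
    "residual",
    "infinite_dilution",
]


@dataclass(frozen=True)
class MixtureComposition:
    """Mole and segment (volume) fractions of a binary mixture."""

    x1: float
    x2: float
    phi1: float
    phi2: float
    r1: float
    r2: float

    @classmethod
    def from_mole_fraction(cls, x1: float, r1: float, r2: float) -> "MixtureComposition":
        if not 0.0 <= x1 <= 1.0:
            raise DomainError(f"mole fraction must lie in [0, 1], got {x1}")
        if not (r1 > 0 and r2 > 0):
            raise DomainError("segment numbers must be positive")
        x2 = 1.0 - x1
        r = x1 * r1 + x2 * r2
        return cls(x1=x1, x2=x2, phi1=x1 * r1 / r, phi2=x2 * r2 / r, r1=r1, r2=r2)

    @property
    def r_total(self) -> float:
        return self.x1 * self.r1 + self.x2 * self.r2


@dataclass(frozen=True)
class ActivityBreakdown:
    """Decomposed natural-log activity coefficient of the solute (index 1)."""

    ln_gamma_C: float
    ln_gamma_VE: float
    ln_gamma_S: float
    ln_gamma_H: float
    ln_gamma_res: float
    ln_gamma_total: float
    chi12: float


def combinatorial(x1: float, r1: float, r2: float) -> float:
    """Flory--Huggins combinatorial term ln(phi1/x1) + (1 - r1/r2)*phi2.

    The x1 -> 0 limit, ln(r1/r2) + 1 - r1/r2, is returned exactly at x1 = 0.
    """
    comp = MixtureComposition.from_mole_fraction(x1, r1, r2)
    if x1 == 0.0:
        rho = r1 / r2
        return math.log(rho) + 1.0 - rho
    # phi1/x1 = r1 / (x1 r1 + x2 r2), finite for all x1
    return math.log(r1 / comp.r_total) + (1.0 - r1 / r2) * comp.phi2


def _ve_bracket(lser1: LSERDescriptors, lser2: LSERDescriptors) -> float:
    a1 = math.sqrt(DISPERSION_VX_COEFF + lser1.E / lser1.Vx)
    a2 = math.sqrt(DISPERSION_VX_COEFF + lser2.E / lser2.Vx)
    return (a1 - a2) ** 2


def _s_bracket(lser1: LSERDescriptors, lser2: LSERDescriptors) -> float:
    a1 = math.sqrt(lser1.S / lser1.Vx)
    a2 = math.sqrt(lser2.S / lser2.Vx)
    return (a1 - a2) ** 2


def ve_contribution(lser1: LSERDescriptors, lser2: LSERDescriptors,
                    phi2: float, T: float = T_REF) -> float:
    """Dispersion/refractivity (volume--energy) contribution, always >= 0.

    10000 * Vx1 * phi2^2 / (R T) * (sqrt(3.1 + E1/Vx1) - sqrt(3.1 + E2/Vx2))^2
    """
    if not T > 0:
        raise DomainError(f"temperature must be positive, got {T}")
    return PSP_SCALE_SQ * lser1.Vx * phi2 ** 2 / (R * T) * _ve_bracket(lser1, lser2)


def s_contribution(lser1: LSERDescriptors, lser2: LSERDescriptors,
                   phi2: float, T: float = T_REF) -> float:
    """Polarity contribution, always >= 0.

    10000 * Vx1 * phi2^2 / (R T) * (sqrt(S1/Vx1) - sqrt(S2/Vx2))^2
    """
    if not T > 0:
        raise DomainError(f"temperature must be positive, got {T}")
    return PSP_SCALE_SQ * lser1.Vx * phi2 ** 2 / (R * T) * _s_bracket(lser1, lser2)


def hb_contribution(x1: float, lser1: LSERDescriptors, lser2: LSERDescriptors,
                    T: float = T_REF) -> float:
    """Hydrogen-bonding contribution to ln gamma_1 by Veytsman statistics.

    Evaluated from the mixture association state minus the pure-solute state:

        [r1*nu_H - ln(x1/(x1 - v11 - v12)) - ln(x1/(x1 - v11 - v21))]_mixture
        - [v11 + 2 ln(1 - v11)]_pure1

    with v_ij = r*nu_ij (bond counts per mole of molecules).  Terms vanish
    automatically for pairs that cannot form.  Zero when no species has both
    a donor facing an acceptor anywhere in the mixture.
    """
    if not 0.0 < x1 <= 1.0:
        raise DomainError(f"x1 must lie in (0, 1], got {x1}")
    r1 = lser1.r
    state = solve_equilibrium([x1, 1.0 - x1], [lser1, lser2], T)
    r = state.r_total
    v = r * state.nu  # v[i, j] = r * nu_ij
    mixture = r1 * state.nu_H
    mixture -= math.log(x1 / (x1 - v[0, 0] - v[0, 1]))
    mixture -= math.log(x1 / (x1 - v[0, 0] - v[1, 0]))

    pure = 0.0
    pe = pair_energy(lser1.A, lser1.B, T)
    if pe.exists:
        v11p = pure_bond_fraction(r1, pe.G_HB, T)
        pure = v11p + 2.0 * math.log(1.0 - v11p)
    return mixture - pure


def residual(lser1: LSERDescriptors, lser2: LSERDescriptors, x1: float,
             T: float = T_REF) -> ActivityBreakdown:
    """Full activity-coefficient breakdown of solute 1 at mole fraction x1.

    The residual part is the sum of the VE, S and H contributions and defines
    chi12 = ln_gamma_res / (r1 * phi2^2) (NaN in the pure-solute limit).
    """
    comp = MixtureComposition.from_mole_fraction(x1, lser1.r, lser2.r)
    ln_C = combinatorial(x1, comp.r1, comp.r2)
    ln_VE = ve_contribution(lser1, lser2, comp.phi2, T)
    ln_S = s_contribution(lser1, lser2, comp.phi2, T)
    ln_H = hb_contribution(x1, lser1, lser2, T) if x1 > 0 else _hb_inf(lser1, lser2, T)
    ln_res = ln_VE + ln_S + ln_H
    chi12 = ln_res / (comp.r1 * comp.phi2 ** 2) if comp.phi2 > 0 else float("nan")
    return ActivityBreakdown(
        ln_gamma_C=ln_C,
        ln_gamma_VE=ln_VE,
        ln_gamma_S=ln_S,
        ln_gamma_H=ln_H,
        ln_gamma_res=ln_res,
        ln_gamma_total=ln_C + ln_res,
        chi12=chi12,
    )


def _hb_inf(lser1: LSERDescriptors, lser2: LSERDescriptors, T: float,
            r1: float | None = None, r2: float | None = None) -> float:
    """Analytic x1 -> 0 limit of the hydrogen-bonding contribution.

    Built from the solvent's pure self-association fraction v22 = r2*nu_22
    and the cross-association constants A_ij = r2 * exp(G_HB,ij/(R T)):

        r1*v22/r2 - ln((1 + A12 - v22)/A12) - ln((1 + A21 - v22)/A21)
        - [v11 + 2 ln(1 - v11)]_pure1

    where each cross term appears only if the corresponding donor->acceptor
    pair exists.
    """
    r1 = lser1.r if r1 is None else r1
    r2 = lser2.r if r2 is None else r2
    pe22 = pair_energy(lser2.A, lser2.B, T)
    v22 = pure_bond_fraction(r2, pe22.G_HB, T) if pe22.exists else 0.0
    out = r1 * v22 / r2
    pe12 = pair_energy(lser1.A, lser2.B, T)  # solute donor -> solvent acceptor
    if pe12.exists:
        A12 = r2 * math.exp(pe12.G_HB / (R * T))
        out -= math.log((1.0 + A12 - v22) / A12)
    pe21 = pair_energy(lser2.A, lser1.B, T)  # solvent donor -> solute acceptor
    if pe21.exists:
        A21 = r2 * math.exp(pe21.G_HB / (R * T))
        out -= math.log((1.0 + A21 - v22) / A21)
    pe11 = pair_energy(lser1.A, lser1.B, T)
    if pe11.exists:
        v11p = pure_bond_fraction(r1, pe11.G_HB, T)
        out -= v11p + 2.0 * math.log(1.0 - v11p)
    return out


def infinite_dilution(lser_solute: LSERDescriptors, lser_solvent: LSERDescriptors,
                      T: float = T_REF, r1: float | None = None,
                      r2: float | None = None) -> float:
    """Analytic residual ln gamma of solute 1 at infinite dilution in solvent 2.

    phi2 -> 1, x2 -> 1: the quadratic VE and S terms are evaluated at
    phi2 = 1 and the hydrogen-bonding term reduces to closed form (solvent
    self-association plus cross-association constants).  Equals
    r1 * chi12 at infinite dilution.
    """
    if not T > 0:
        raise DomainError(f"temperature must be positive, got {T}")
    ln_VE = ve_contribution(lser_solute, lser_solvent, 1.0, T)
    ln_S = s_contribution(lser_solute, lser_solvent, 1.0, T)
    return ln_VE + ln_S + _hb_inf(lser_solute, lser_solvent, T, r1=r1, r2=r2)
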