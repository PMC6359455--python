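"""Hydrogen-bonding association thermodynamics.

A molecule with nonzero acidity descriptor A carries one proton-donor group;
nonzero basicity B carries one acceptor group.  Donor--acceptor pair (i, j)
forms with free energy

    G_HB,ij = -(30450 - 35.1*T) * sqrt(A_i * B_j)   [J/mol]

(the enthalpic and entropic coefficients are anchored to the lower-alkanol
reference E_HB = -23000 J/mol, S_HB = -26.5 J/(K mol)).  The equilibrium
number of bonds follows Veytsman's combinatorial statistics: writing
nu_ij = N_ij / (r N) for the reduced bond numbers (per total lattice
segment), the free-energy minimum satisfies

    nu_ij / (nu_i0 * nu_0j) = exp(-G_HB,ij / (R T))

subject to the donor and acceptor balances

    nu_i0 = x_i/r - sum_j nu_ij ,   nu_0j = x_j/r - sum_i nu_ij .

For a pure self-associating fluid this reduces to the closed-form quadratic
of :func:`pure_bond_fraction`.  The multi-species system is solved by cyclic
per-pair exact updates (each update is the scalar quadratic, i.e. an exact
coordinate minimization of the convex association free energy), with an
L-BFGS-B minimization of that free energy as a fallback.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .constants import EHB_COEFF, R, SHB_COEFF, T_REF
from .descriptors import LSERDescriptors, PSPSet, psp_from_lser
from .exceptions import ConvergenceError, DomainError

__all__ = [
    "HBondPairEnergy",
    "HBondState",
    "pair_energy",
    "pure_bond_fraction",
    "hb_ced",
    "solve_equilibrium",
    "association_free_energy",
    "full_psp",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class HBondPairEnergy:
    """Energetics of one donor->acceptor hydrogen bond at temperature T."""

    G_HB: float  # J/mol
    E_HB: float  # J/mol
    S_HB: float  # J/(K mol)
    exists: bool


def pair_energy(A_i: float, B_j: float, T: float) -> HBondPairEnergy:
    """Formation energetics of a bond between donor of acidity ``A_i`` and
    acceptor of basicity ``B_j``.

    The printed product of acidity and basicity enters as sqrt(A*B); with
    w = sqrt(A_i*B_j):  E_HB = -30450*w,  S_HB = -35.1*w,
    G_HB = -(30450 - 35.1*T)*w.  A pair with w = 0 does not exist.
    """
    if A_i < 0 or B_j < 0:
        raise DomainError(f"descriptors must be nonnegative, got A={A_i}, B={B_j}")
    if not T > 0:
        raise DomainError(f"temperature must be positive, got {T}")
    w = math.sqrt(A_i * B_j)
    if w == 0.0:
        return HBondPairEnergy(0.0, 0.0, 0.0, False)
    return HBondPairEnergy(
        G_HB=-(EHB_COEFF - SHB_COEFF * T) * w,
        E_HB=-EHB_COEFF * w,
        S_HB=-SHB_COEFF * w,
        exists=True,
    )


def pure_bond_fraction(r: float, G_HB: float | HBondPairEnergy, T: float) -> float:
    """Bonded fraction r*nu_11 = N_11/N of a pure self-associating fluid.

    With A11 = r * exp(G_HB / (R T)) the closed form is

        r*nu_11 = (A11 + 2 - sqrt(A11*(A11 + 4))) / 2  in [0, 1].

    Passing a nonexistent :class:`HBondPairEnergy` returns 0.
    """
    if isinstance(G_HB, HBondPairEnergy):
        if not G_HB.exists:
            return 0.0
        G_HB = G_HB.G_HB
    if not r > 0:
        raise DomainError(f"segment number must be positive, got {r}")
    A11 = r * math.exp(G_HB / (R * T))
    return (A11 + 2.0 - math.sqrt(A11 * (A11 + 4.0))) / 2.0


def hb_ced(r: float, bonded_fraction: float, E_HB: float, Vm: float) -> tuple[float, float]:
    """Hydrogen-bonding cohesive energy density and sigma_hb.

    ced_HB = -(r*nu_11) * E_HB / Vm  in J/cm^3 = MPa;  sigma_hb = sqrt(ced_HB).

    Parameters
    ----------
    r, bonded_fraction : float
        Kept separate from E_HB for clarity; ``bonded_fraction`` is r*nu_11.
    E_HB : float
        Bond formation energy, J/mol (nonpositive).
    Vm : float
        Molar volume, cm^3/mol.
    """
    if not Vm > 0:
        raise DomainError(f"molar volume must be positive, got {Vm}")
    ced = -bonded_fraction * E_HB / Vm
    return ced, math.sqrt(max(ced, 0.0))


def full_psp(lser: LSERDescriptors, Vm: float, T: float = T_REF,
             name: str = "compound") -> PSPSet:
    """Complete PSP set including the hydrogen-bonding component.

    sigma_hb is nonzero only for self-associating (homosolvating) compounds,
    i.e. those with both A > 0 and B > 0.
    """
    base = psp_from_lser(lser, Vm, name=name)
    pair = pair_energy(lser.A, lser.B, T)
    if not pair.exists:
        return base
    frac = pure_bond_fraction(lser.r, pair.G_HB, T)
    _, sigma_hb = hb_ced(lser.r, frac, pair.E_HB, Vm)
    return PSPSet(base.sigma_d, base.sigma_p, base.sigma_Ga, base.sigma_Gb, sigma_hb)


# ---------------------------------------------------------------------------
# Multi-species association equilibrium
# ---------------------------------------------------------------------------

@dataclass
class HBondState:
    """Equilibrium reduced hydrogen-bond numbers of a mixture.

    All nu quantities are per total lattice segment (N_ij / (r N)).
    """

    nu: np.ndarray                 # nu[i, j], donor species i x acceptor species j
    nu_free_donors: np.ndarray     # nu_i0
    nu_free_acceptors: np.ndarray  # nu_0j
    r_total: float                 # mixture-average segment number
    converged: bool
    iterations: int
    residual: float

    @property
    def nu_H(self) -> float:
        """Total reduced number of hydrogen bonds."""
        return float(self.nu.sum())


def _pair_quadratic(K: float, d: float, a: float) -> float:
    """Exact solution of nu = (d - nu)(a - nu) K on [0, min(d, a)].

    This is the single-pair stationarity condition with all other pairs held
    fixed; d and a are the donor/acceptor amounts available to this pair.
    """
    if d <= 0.0 or a <= 0.0 or K <= 0.0:
        return 0.0
    b = 1.0 + K * (d + a)
    disc = b * b - 4.0 * K * K * d * a
    # numerically stable smaller root of K nu^2 - b nu + K d a = 0
    return 2.0 * K * d * a / (b + math.sqrt(max(disc, 0.0)))


def association_free_energy(nu: np.ndarray, donors: np.ndarray,
                            acceptors: np.ndarray, G_over_RT: np.ndarray) -> float:
    """Veytsman association free energy (per total segment, units of RT).

    Constant terms independent of nu are dropped; the gradient with respect
    to an existing nu_ij vanishes exactly at the equilibrium condition
    nu_ij = nu_i0 * nu_0j * exp(-G_ij/RT).  Convex on the feasible set.
    """
    def xlogx(v):
        v = np.asarray(v, dtype=float)
        out = np.zeros_like(v)
        mask = v > 0
        out[mask] = v[mask] * np.log(v[mask]) - v[mask]
        return out

    nu_i0 = donors - nu.sum(axis=1)
    nu_0j = acceptors - nu.sum(axis=0)
    if np.any(nu < -1e-15) or np.any(nu_i0 < -1e-12) or np.any(nu_0j < -1e-12):
        return np.inf
    exist = G_over_RT != 0.0
    f = float(np.sum(nu[exist] * G_over_RT[exist]))
    f += float(np.sum(xlogx(nu[exist])))
    f += float(np.sum(xlogx(nu_i0)) + np.sum(xlogx(nu_0j)))
    return f


def solve_equilibrium(x: Sequence[float], species: Sequence[LSERDescriptors],
                      T: float, max_iter: int = 10000,
                      rtol: float = 1e-14) -> HBondState:
    """Solve the association equilibrium of a multi-species mixture.

    Parameters
    ----------
    x : sequence of mole fractions (must sum to 1).
    species : LSER descriptors per species (A > 0 means one donor group,
        B > 0 one acceptor group).
    T : temperature, K.

    Returns
    -------
    HBondState
        With nu satisfying the minimization conditions and balances.

    Notes
    -----
    Deterministic: cyclic exact per-pair updates (coordinate minimization of
    the convex association free energy); every iterate is feasible.  On the
    rare failure to reach the residual tolerance, the free energy is
    minimized directly (L-BFGS-B) and re-checked.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise DomainError("at least one species is required")
    if len(x) != len(species):
        raise DomainError("x and species must have equal length")
    if abs(x.sum() - 1.0) > 1e-9:
        raise DomainError(f"mole fractions must sum to 1, got {x.sum()}")
    n = len(x)
    r_i = np.array([s.r for s in species])
    r_total = float(np.dot(x, r_i))

    donors = np.where([s.A > 0 for s in species], x / r_total, 0.0)
    acceptors = np.where([s.B > 0 for s in species], x / r_total, 0.0)
    K = np.zeros((n, n))
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            pe = pair_energy(si.A, sj.B, T)
            if pe.exists and donors[i] > 0 and acceptors[j] > 0:
                K[i, j] = math.exp(-pe.G_HB / (R * T))
    pairs = [(i, j) for i in range(n) for j in range(n) if K[i, j] > 0]

    nu = np.zeros((n, n))
    iterations = 0
    converged = not pairs
    for sweep in range(max_iter):
        iterations = sweep + 1
        delta = 0.0
        for i, j in pairs:
            d_avail = donors[i] - nu[i].sum() + nu[i, j]
            a_avail = acceptors[j] - nu[:, j].sum() + nu[i, j]
            new = _pair_quadratic(K[i, j], d_avail, a_avail)
            delta = max(delta, abs(new - nu[i, j]) / (abs(nu[i, j]) + 1e-300))
            nu[i, j] = new
        if delta <= rtol:
            converged = True
            break
        if sweep >= 200 and delta < 1e-4:
            break  # slow linear tail; hand over to the Newton polish

    residual = _max_residual(nu, donors, acceptors, K, pairs)
    if pairs and residual > 1e-15:
        nu, residual = _newton_polish(nu, donors, acceptors, K, pairs)
        converged = True
    if pairs and residual > 1e-10:
        nu, residual, converged = _fallback_minimize(nu, donors, acceptors, K, pairs)
        if not converged:
            raise ConvergenceError(
                "hydrogen-bond equilibrium did not converge",
                residual=residual, iterations=iterations,
            )
    logger.debug("hbond equilibrium: %d sweeps, residual %.3e", iterations, residual)

    return HBondState(
        nu=nu,
        nu_free_donors=donors - nu.sum(axis=1),
        nu_free_acceptors=acceptors - nu.sum(axis=0),
        r_total=r_total,
        converged=converged,
        iterations=iterations,
        residual=residual,
    )


def _max_residual(nu, donors, acceptors, K, pairs) -> float:
    """Max violation of nu_ij = nu_i0 * nu_0j * K_ij over existing pairs."""
    if not pairs:
        return 0.0
    nu_i0 = donors - nu.sum(axis=1)
    nu_0j = acceptors - nu.sum(axis=0)
    return max(abs(nu[i, j] - nu_i0[i] * nu_0j[j] * K[i, j]) for i, j in pairs)


def _newton_polish(nu, donors, acceptors, K, pairs):
    """Newton refinement of nu_ij = nu_i0 * nu_0j * K_ij to machine precision.

    The cyclic sweeps land close to the fixed point; a few Newton steps on
    the residual system (analytic Jacobian) remove the linear tail.
    """
    from scipy.optimize import root

    idx = {pair: k for k, pair in enumerate(pairs)}

    def unpack(z):
        m = np.zeros_like(nu)
        for (i, j), k in idx.items():
            m[i, j] = z[k]
        return m

    def fun(z):
        m = unpack(z)
        nu_i0 = donors - m.sum(axis=1)
        nu_0j = acceptors - m.sum(axis=0)
        return np.array([m[i, j] - nu_i0[i] * nu_0j[j] * K[i, j] for i, j in pairs])

    def jac(z):
        m = unpack(z)
        nu_i0 = donors - m.sum(axis=1)
        nu_0j = acceptors - m.sum(axis=0)
        J = np.zeros((len(pairs), len(pairs)))
        for (i, j), a in idx.items():
            for (k, l), b in idx.items():
                J[a, b] = (1.0 if a == b else 0.0)
                if k == i:
                    J[a, b] += K[i, j] * nu_0j[j]
                if l == j:
                    J[a, b] += K[i, j] * nu_i0[i]
        return J

    z0 = np.array([nu[i, j] for i, j in pairs])
    sol = root(fun, z0, jac=jac, method="hybr", tol=1e-15)
    z = np.clip(sol.x, 0.0, None)
    nu_new = unpack(z)
    residual = _max_residual(nu_new, donors, acceptors, K, pairs)
    old = _max_residual(nu, donors, acceptors, K, pairs)
    if residual <= old:
        return nu_new, residual
    return nu, old


def _fallback_minimize(nu, donors, acceptors, K, pairs):
    from scipy.optimize import minimize

    G_over_RT = np.where(K > 0, -np.log(np.where(K > 0, K, 1.0)), 0.0)

    def unpack(z):
        m = np.zeros_like(nu)
        for k, (i, j) in enumerate(pairs):
            m[i, j] = z[k]
        return m

    def fun(z):
        return association_free_energy(unpack(z), donors, acceptors, G_over_RT)

    z0 = np.array([nu[i, j] for i, j in pairs])
    bounds = [(1e-300, min(donors[i], acceptors[j])) for i, j in pairs]
    res = minimize(fun, z0, method="L-BFGS-B", bounds=bounds,
                   options={"ftol": 1e-18, "gtol": 1e-14, "maxiter": 5000})
    nu_new = unpack(res.x)
    residual = _max_residual(nu_new, donors, acceptors, K, pairs)
    return nu_new, residual, residual <= 1e-10
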