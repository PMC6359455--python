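"""Hydrogen-bond energetics and the association equilibrium solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize

from psptherm import (
    LSERDescriptors,
    full_psp,
    hb_ced,
    pair_energy,
    pure_bond_fraction,
    segments_from_mcgowan,
    solve_equilibrium,
)
from psptherm.constants import R
from psptherm.exceptions import DomainError

T = 298.15


# ---------------------------------------------------------------------------
# Independent oracle: Veytsman association free energy, minimized numerically.
# Written directly from the statistics (bond counts per total segment), not
# from the package's update equations.
# ---------------------------------------------------------------------------

def oracle_free_energy(nu, donors, acceptors, G_matrix, T):
    """Association free energy per segment, in units of RT (constants dropped)."""
    def xlx(v):
        return v * math.log(v) - v if v > 0 else 0.0

    f = 0.0
    free_d = donors.copy()
    free_a = acceptors.copy()
    for (i, j), g in G_matrix.items():
        f += nu[i, j] * g / (R * T) + xlx(nu[i, j])
        free_d[i] -= nu[i, j]
        free_a[j] -= nu[i, j]
    if np.any(free_d < 0) or np.any(free_a < 0):
        return np.inf
    f += sum(xlx(v) for v in free_d) + sum(xlx(v) for v in free_a)
    return f


def oracle_minimize(x, species, T):
    """Brute-force minimization of the association free energy: damped Newton
    with backtracking on the strictly convex objective (analytic gradient and
    Hessian derived directly from the free-energy expression)."""
    x = np.asarray(x, float)
    r_i = np.array([s.r for s in species])
    r = float(x @ r_i)
    donors = np.array([xi / r if s.A > 0 else 0.0 for xi, s in zip(x, species)])
    acceptors = np.array([xi / r if s.B > 0 else 0.0 for xi, s in zip(x, species)])
    G = {}
    for i, si in enumerate(species):
        for j, sj in enumerate(species):
            if si.A > 0 and sj.B > 0 and donors[i] > 0 and acceptors[j] > 0:
                G[(i, j)] = -(30450.0 - 35.1 * T) * math.sqrt(si.A * sj.B)
    pairs = list(G)
    if not pairs:
        return np.zeros((len(x), len(x)))

    def unpack(z):
        nu = np.zeros((len(x), len(x)))
        for k, (i, j) in enumerate(pairs):
            nu[i, j] = z[k]
        return nu

    def fun_grad(z):
        nu = unpack(z)
        free_d = donors - nu.sum(axis=1)
        free_a = acceptors - nu.sum(axis=0)
        if np.any(z <= 0):
            return np.inf, np.zeros_like(z)
        f = oracle_free_energy(nu, donors, acceptors, G, T)
        g = np.array([
            G[(i, j)] / (R * T)
            + math.log(max(nu[i, j], 1e-300))
            - math.log(max(free_d[i], 1e-300))
            - math.log(max(free_a[j], 1e-300))
            for (i, j) in pairs
        ])
        return f, g

    def hess(z):
        nu = unpack(z)
        free_d = donors - nu.sum(axis=1)
        free_a = acceptors - nu.sum(axis=0)
        H = np.zeros((len(pairs), len(pairs)))
        for a, (i, j) in enumerate(pairs):
            for b, (k, l) in enumerate(pairs):
                if a == b:
                    H[a, b] += 1.0 / max(nu[i, j], 1e-300)
                if k == i:
                    H[a, b] += 1.0 / max(free_d[i], 1e-300)
                if l == j:
                    H[a, b] += 1.0 / max(free_a[j], 1e-300)
        return H

    row_count = {i: sum(1 for (a, _) in pairs if a == i) for i, _ in pairs}
    col_count = {j: sum(1 for (_, b) in pairs if b == j) for _, j in pairs}
    z = np.array([0.5 * min(donors[i] / row_count[i], acceptors[j] / col_count[j])
                  for i, j in pairs])
    f, g = fun_grad(z)
    for _ in range(200):
        step = np.linalg.solve(hess(z), g)
        alpha = 1.0
        while alpha > 1e-14:
            z_new = z - alpha * step
            f_new, g_new = fun_grad(z_new)
            if np.isfinite(f_new) and f_new <= f:
                break
            alpha *= 0.5
        if alpha <= 1e-14:
            break
        moved = np.max(np.abs(z - z_new))
        z, f, g = z_new, f_new, g_new
        if moved < 1e-16:
            break
    return unpack(z)


# ---------------------------------------------------------------------------
# Pair energetics
# ---------------------------------------------------------------------------

class TestPairEnergy:
    def test_no_donor_means_no_bond(self):
        pe = pair_energy(0.0, 0.7, T)
        assert not pe.exists
        assert (pe.G_HB, pe.E_HB, pe.S_HB) == (0.0, 0.0, 0.0)

    def test_ethanol_self_association_energetics(self):
        pe = pair_energy(0.37, 0.48, T)
        assert pe.G_HB == pytest.approx(-8422, abs=1.0)
        assert pe.E_HB == pytest.approx(-12833, abs=1.0)

    def test_unit_descriptor_free_energy(self):
        assert pair_energy(1.0, 1.0, T).G_HB == pytest.approx(-19984.9, abs=0.1)

    def test_negative_descriptor_rejected(self):
        with pytest.raises(DomainError):
            pair_energy(-0.1, 0.5, T)

    @given(A=st.floats(0.01, 2.0), B=st.floats(0.01, 2.0), temp=st.floats(250, 400))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_gibbs_helmholtz_identity(self, A, B, temp):
        pe = pair_energy(A, B, temp)
        assert pe.G_HB == pytest.approx(pe.E_HB - temp * pe.S_HB, rel=1e-9)

    @given(Vm=st.floats(20, 1500), A=st.floats(0.01, 2.0), B=st.floats(0.01, 2.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_free_energy_matches_psp_product_at_reference(self, Vm, A, B):
        """2 * Vm * sigma_Ga * sigma_Gb = 20000 * sqrt(A*B) exactly."""
        from psptherm import psp_from_lser
        psp = psp_from_lser(LSERDescriptors(Vx=1.0, A=A, B=B), Vm)
        assert 2 * Vm * psp.sigma_Ga * psp.sigma_Gb == pytest.approx(
            20000 * math.sqrt(A * B), rel=1e-9)


# ---------------------------------------------------------------------------
# Pure-fluid bond fraction and cohesive energy
# ---------------------------------------------------------------------------

class TestPureFluid:
    def test_absent_bond_gives_zero_fraction(self):
        assert pure_bond_fraction(2.0, pair_energy(0.0, 1.0, T), T) == 0.0

    def test_ethanol_bonded_fraction(self):
        r = segments_from_mcgowan(0.449)
        pe = pair_energy(0.37, 0.48, T)
        assert pure_bond_fraction(r, pe.G_HB, T) == pytest.approx(0.767, abs=1e-3)

    def test_saturation_limit(self):
        assert pure_bond_fraction(2.0, -1e6, T) == pytest.approx(1.0, abs=1e-12)

    @given(r=st.floats(0.5, 50), G=st.floats(-40000, 0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fraction_stays_in_unit_interval(self, r, G):
        assert 0.0 <= pure_bond_fraction(r, G, T) <= 1.0

    def test_ethanol_hb_cohesive_energy(self):
        ced, sigma = hb_ced(2.108, 0.767, -12833.0, 58.6)
        assert ced == pytest.approx(168, abs=1.0)
        assert sigma == pytest.approx(13.0, abs=0.05)

    def test_non_associating_compound_has_zero_sigma_hb(self):
        ced, sigma = hb_ced(2.0, 0.0, 0.0, 100.0)
        assert ced == 0.0 and sigma == 0.0

    def test_carvedilol_chained_sigma_hb(self):
        """Full chain from descriptors: ced ~ 70.5 MPa, sigma_hb ~ 8.40."""
        lser = LSERDescriptors(Vx=3.10, E=3.08, S=3.19, A=0.50, B=1.45)
        psp = full_psp(lser, 325.3, T)
        assert psp.sigma_hb == pytest.approx(8.40, abs=0.01)
        assert psp.sigma_hb ** 2 == pytest.approx(70.5, abs=0.2)


# ---------------------------------------------------------------------------
# Mixture equilibrium
# ---------------------------------------------------------------------------

class TestEquilibrium:
    def test_inert_mixture_has_no_bonds(self):
        species = [LSERDescriptors(Vx=1.0, A=0.5), LSERDescriptors(Vx=1.0, A=0.3)]
        state = solve_equilibrium([0.4, 0.6], species, T)  # donors but no acceptors
        assert np.all(state.nu == 0.0)
        assert state.nu_H == 0.0

    def test_single_species_matches_closed_form(self):
        lser = LSERDescriptors(Vx=0.449, E=0.25, S=0.419, A=0.37, B=0.48)
        state = solve_equilibrium([1.0], [lser], T)
        frac = pure_bond_fraction(lser.r, pair_energy(lser.A, lser.B, T).G_HB, T)
        assert state.nu[0, 0] == pytest.approx(frac / lser.r, abs=1e-10)

    def test_ethanol_alkane_beats_grid_search(self):
        """The solver's free energy is below every point of a 200-point grid
        over the feasible self-association interval."""
        eth = LSERDescriptors(Vx=0.449, E=0.25, S=0.419, A=0.37, B=0.48)
        hep = LSERDescriptors(Vx=1.095)
        x = np.array([0.5, 0.5])
        state = solve_equilibrium(x, [eth, hep], T)
        r = state.r_total
        donors = np.array([0.5 / r, 0.0])
        acceptors = np.array([0.5 / r, 0.0])
        G = {(0, 0): pair_energy(eth.A, eth.B, T).G_HB}
        f_solver = oracle_free_energy(state.nu, donors, acceptors, G, T)
        upper = min(donors[0], acceptors[0])
        for nu11 in np.linspace(1e-9, upper * (1 - 1e-9), 200):
            nu = np.zeros((2, 2))
            nu[0, 0] = nu11
            assert f_solver <= oracle_free_energy(nu, donors, acceptors, G, T) + 1e-12

    def test_two_species_matches_free_energy_minimization(self, rng):
        """Iterative solution equals direct numerical minimization of the
        association free energy on random parameter draws."""
        for _ in range(10):
            s1 = LSERDescriptors(Vx=float(rng.uniform(0.3, 4)),
                                 A=float(rng.uniform(0.05, 1.2)),
                                 B=float(rng.uniform(0.05, 1.2)))
            s2 = LSERDescriptors(Vx=float(rng.uniform(0.3, 4)),
                                 A=float(rng.uniform(0.05, 1.2)),
                                 B=float(rng.uniform(0.05, 1.2)))
            x1 = float(rng.uniform(0.1, 0.9))
            state = solve_equilibrium([x1, 1 - x1], [s1, s2], T)
            nu_oracle = oracle_minimize([x1, 1 - x1], [s1, s2], T)
            assert np.max(np.abs(state.nu - nu_oracle)) < 1e-8

    def test_balances_and_minimization_conditions(self, rng):
        """Donor/acceptor balances and the per-pair equilibrium condition
        hold to 1e-10 on random mixtures."""
        for _ in range(20):
            species = [
                LSERDescriptors(Vx=float(rng.uniform(0.3, 5)),
                                A=float(rng.choice([0.0, rng.uniform(0.05, 1.5)])),
                                B=float(rng.choice([0.0, rng.uniform(0.05, 1.5)])))
                for _ in range(2)
            ]
            x1 = float(rng.uniform(0.05, 0.95))
            x = [x1, 1 - x1]
            state = solve_equilibrium(x, species, T)
            r = state.r_total
            for i in range(2):
                assert state.nu_free_donors[i] == pytest.approx(
                    (x[i] / r if species[i].A > 0 else 0.0) - state.nu[i].sum(), abs=1e-10)
                assert state.nu_free_acceptors[i] == pytest.approx(
                    (x[i] / r if species[i].B > 0 else 0.0) - state.nu[:, i].sum(), abs=1e-10)
            for i in range(2):
                for j in range(2):
                    if species[i].A > 0 and species[j].B > 0:
                        K = math.exp(-pair_energy(species[i].A, species[j].B, T).G_HB / (R * T))
                        assert abs(state.nu[i, j] - state.nu_free_donors[i]
                                   * state.nu_free_acceptors[j] * K) < 1e-10

    def test_dilution_reduces_solvent_self_association(self):
        eth = LSERDescriptors(Vx=0.449, E=0.25, S=0.419, A=0.37, B=0.48)
        hep = LSERDescriptors(Vx=1.095)
        previous = np.inf
        for x_inert in [0.0, 0.2, 0.4, 0.6, 0.8, 0.95]:
            state = solve_equilibrium([x_inert, 1 - x_inert], [hep, eth], T)
            assert state.nu[1, 1] < previous
            previous = state.nu[1, 1]

    def test_mole_fractions_must_sum_to_one(self):
        with pytest.raises(DomainError):
            solve_equilibrium([0.5, 0.4], [LSERDescriptors(Vx=1.0)] * 2, T)
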