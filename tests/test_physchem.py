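"""Unit and property tests for the pair-interaction and electrostatics layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lnpkmc import physchem
from lnpkmc.physchem import (Environment, Formulation, InteractionParams,
                             ParticleState, StaleCacheError,
                             UnscreenedRegimeError)

ENV = Environment()
FORM = Formulation()
IP = InteractionParams()


def make_particle(r0=9.0, rna=0, form=FORM):
    """Particle of target bare radius built from proportional lipid counts."""
    v_lipid = (1 - form.fw) * 4 / 3 * math.pi * r0**3 - rna * form.rna_volume
    n_lip = v_lipid / form.mean_lipid_volume
    counts = n_lip * np.asarray(form.molar_fractions)
    return ParticleState.from_counts(counts, rna, form)


class TestScreening:
    def test_debye_length_standard_values(self):
        # rule-of-thumb 0.304 nm / sqrt(I) for 1:1 salt in water at 25 C
        assert physchem.debye_length(ENV.evolve(csalt=0.15)) == pytest.approx(
            0.304 / math.sqrt(0.15), rel=0.02
        )
        assert physchem.debye_length(ENV.evolve(csalt=0.025)) == pytest.approx(
            1.92, abs=0.02
        )

    def test_debye_length_monotone_vanishing(self):
        lds = [physchem.debye_length(ENV.evolve(csalt=c))
               for c in (0.01, 0.1, 1.0, 10.0)]
        assert all(a > b for a, b in zip(lds, lds[1:]))
        assert lds[-1] < 0.1

    def test_unscreened_regime_signalled(self):
        with pytest.raises(UnscreenedRegimeError):
            physchem.debye_length(ENV.evolve(csalt=0.0))


class TestFloryRadius:
    def test_peg2000_value(self):
        assert physchem.flory_radius(2000.0) == pytest.approx(3.6, abs=0.1)

    def test_single_monomer(self):
        assert physchem.flory_radius(44.0) == pytest.approx(0.37)

    def test_peg5000_value(self):
        assert physchem.flory_radius(5000.0) == pytest.approx(
            0.37 * (5000 / 44) ** 0.6, rel=1e-12
        )

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            physchem.flory_radius(2000.0, a=-1.0)
        with pytest.raises(ValueError):
            physchem.flory_radius(10.0)  # below one monomer


class TestCollisionRate:
    def test_equal_radii_size_free(self):
        # equal sizes: K = 8kBT/3eta, independent of radius
        k5 = physchem.collision_rate(5.0, 5.0, ENV)
        k50 = physchem.collision_rate(50.0, 50.0, ENV)
        assert k5 == pytest.approx(k50, rel=1e-12)
        expected = 8 * 1.380649e-23 * 298 / (3 * 8.9e-4) * 1e27
        assert k5 == pytest.approx(expected, rel=1e-9)
        assert k5 == pytest.approx(1.23e10, rel=0.01)

    def test_size_asymmetry_ratio(self):
        ratio = physchem.collision_rate(5.0, 20.0, ENV) / \
            physchem.collision_rate(10.0, 10.0, ENV)
        assert ratio == pytest.approx((25.0**2 / 100.0) / 4.0, rel=1e-12)

    def test_rejects_nonpositive_radius(self):
        with pytest.raises(ValueError):
            physchem.collision_rate(0.0, 5.0, ENV)


class TestPegBarrier:
    def test_zero_without_peg(self):
        form = Formulation(molar_fractions=(0.5, 0.115, 0.385, 0.0))
        pi = make_particle(form=form)
        assert physchem.peg_barrier(pi, pi, form) == 0.0

    def test_equal_size_closed_form(self):
        pi = make_particle(9.0)
        rf = FORM.flory_radius
        expected = 2 * math.pi * (rf**3 / FORM.v0) * (1 - FORM.fw) \
            * pi.radius**2 * pi.phi_peg
        assert physchem.peg_barrier(pi, pi, FORM) == pytest.approx(
            expected, rel=1e-12
        )

    def test_quadratic_size_scaling(self):
        # doubling both radii at fixed phi quadruples the barrier
        e1 = physchem.pair_peg_barrier(8.0, 8.0, 0.02, 0.02, 3.6, 1.3, 0.2)
        e2 = physchem.pair_peg_barrier(16.0, 16.0, 0.02, 0.02, 3.6, 1.3, 0.2)
        assert e2 == pytest.approx(4 * e1, rel=1e-12)


class TestDlvoEnergy:
    def test_uncharged_is_pure_attraction(self):
        d = np.geomspace(0.3, 30, 50)
        w = physchem.dlvo_energy(d, 9.0, 9.0, ENV, IP, psi_i=0.0, psi_j=0.0)
        assert np.all(w < 0)

    def test_symmetric_closed_form_reduction(self):
        # equal psi and radii: electrostatic part reduces to
        # (eps R psi^2 / 2) ln(1 + exp(-d/lD))  [Hogg-Healy-Fuerstenau]
        psi, r = 2.5, 12.0
        ld = physchem.debye_length(ENV)
        lb = physchem.bjerrum_length(ENV)
        ip0 = InteractionParams(hamaker=0.0)
        for d in (0.3, 1.0, 3.0, 8.0):
            w = physchem.dlvo_energy(d, r, r, ENV, ip0, psi_i=psi, psi_j=psi)
            expected = r * psi**2 / (8 * math.pi * lb) \
                * math.log1p(math.exp(-d / ld))
            assert w == pytest.approx(expected, rel=1e-10)

    def test_vanishes_at_large_separation(self):
        w = physchem.dlvo_energy(1e4, 9.0, 9.0, ENV, IP,
                                 psi_i=3.0, psi_j=3.0)
        assert w == pytest.approx(0.0, abs=1e-3)
        assert w < 0  # van der Waals tail

    def test_rejects_nonpositive_separation(self):
        with pytest.raises(ValueError):
            physchem.dlvo_energy(0.0, 9.0, 9.0, ENV, IP, psi_i=1.0, psi_j=1.0)


class TestDlvoBarrier:
    def test_uncharged_no_barrier(self):
        out = physchem.dlvo_barrier_arrays(9.0, 9.0, 0.0, 0.0, ENV, IP)
        assert out[0] == 0.0

    def test_pure_repulsion_peaks_at_contact(self):
        ip0 = InteractionParams(hamaker=0.0)
        barrier = physchem.dlvo_barrier_arrays(9.0, 9.0, 3.0, 3.0, ENV, ip0)[0]
        at_dmin = physchem.dlvo_energy(ip0.dmin, 9.0, 9.0, ENV, ip0,
                                       psi_i=3.0, psi_j=3.0)
        # monotone decreasing profile: the grid maximum sits at dmin
        assert barrier == pytest.approx(at_dmin, rel=1e-9)

    def test_nonnegative_for_any_inputs(self):
        rng = np.random.default_rng(0)
        ri = rng.uniform(4, 40, 200)
        rj = rng.uniform(4, 40, 200)
        pi = rng.uniform(-5, 5, 200)
        pj = rng.uniform(-5, 5, 200)
        out = physchem.dlvo_barrier_arrays(ri, rj, pi, pj, ENV, IP)
        assert np.all(out >= 0)

    def test_grid_refinement_converged(self):
        # 72-point grid + parabolic apex matches a 4000-point grid closely
        fine = InteractionParams(n_grid=4000)
        rng = np.random.default_rng(1)
        ri = rng.uniform(5, 30, 50)
        psi = rng.uniform(0.5, 4.5, 50)
        coarse_out = physchem.dlvo_barrier_arrays(ri, ri[::-1], psi, psi[::-1],
                                                  ENV, IP)
        fine_out = physchem.dlvo_barrier_arrays(ri, ri[::-1], psi, psi[::-1],
                                                ENV, fine)
        assert np.max(np.abs(coarse_out - fine_out)) < 1e-3


class TestChargeRegulation:
    def test_uncharged_residual_zero(self):
        form = Formulation(charges_per_ionizable=0.0)
        p = make_particle(form=form)
        assert physchem.charge_regulation_residual(0.0, p, form, ENV) == 0.0

    def test_positive_fixed_charge_gives_positive_residual(self):
        p = make_particle(9.0, rna=0)
        assert physchem.charge_regulation_residual(0.0, p, FORM, ENV) > 0

    def test_residual_strictly_decreasing(self):
        p = make_particle(9.0, rna=0)
        vals = [physchem.charge_regulation_residual(x, p, FORM, ENV)
                for x in np.linspace(-6, 6, 41)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_solver_zeroes_residual(self):
        p = make_particle(9.0, rna=5)
        rho, psi = physchem.solve_charge_regulation(p, FORM, ENV)
        assert abs(physchem.charge_regulation_residual(psi, p, FORM, ENV)) \
            < 1e-10
        assert p.psi0 == psi and p.psi_env_tag == ENV.tag()

    def test_uncharged_particle_neutral(self):
        form = Formulation(charges_per_ionizable=0.0)
        p = make_particle(form=form)
        rho, psi = physchem.solve_charge_regulation(p, form,
                                                    ENV.evolve(alpha_rna=0.0))
        assert rho == 0.0 and psi == 0.0

    def test_psi_decreases_with_salt(self):
        p = make_particle(9.0)
        psis = []
        for c in (0.01, 0.025, 0.05, 0.1, 0.15):
            _, psi = physchem.solve_charge_regulation(p, FORM,
                                                      ENV.evolve(csalt=c))
            psis.append(psi)
        assert all(a > b for a, b in zip(psis, psis[1:]))

    def test_rna_lowers_surface_potential(self):
        # loaded particle is closer to neutral than a same-lipid empty one
        empty = make_particle(9.0, rna=0)
        lipid_counts = empty.lipid_counts
        loaded = ParticleState.from_counts(lipid_counts, 20, FORM)
        _, psi_e = physchem.solve_charge_regulation(empty, FORM, ENV)
        _, psi_l = physchem.solve_charge_regulation(loaded, FORM, ENV)
        assert psi_l < psi_e


class TestFusionRate:
    def _pair(self, rna_i=0, rna_j=0):
        pi = make_particle(9.0, rna_i)
        pj = make_particle(9.0, rna_j)
        physchem.solve_charge_regulation(pi, FORM, ENV)
        physchem.solve_charge_regulation(pj, FORM, ENV)
        return pi, pj

    def test_diffusion_only_is_bare_kernel(self):
        pi, pj = self._pair()
        ip = InteractionParams(kernel_mode="diffusion-only")
        v = 1e9
        k = physchem.fusion_rate(pi, pj, ENV, FORM, ip, v)
        assert k == pytest.approx(
            physchem.collision_rate(pi.radius, pj.radius, ENV) / v, rel=1e-12
        )

    def test_huge_barrier_freezes(self):
        pi, pj = self._pair()
        ip = InteractionParams(peg_mult=1e6)
        assert physchem.fusion_rate(pi, pj, ENV, FORM, ip, 1e9) == 0.0

    def test_loaded_pairs_fuse_faster_than_empty(self):
        # RNA neutralizes charge, lowering the electrostatic barrier
        e1, e2 = self._pair(0, 0)
        l1, l2 = self._pair(20, 20)
        k_empty = physchem.fusion_rate(e1, e2, ENV, FORM, IP, 1e9)
        k_loaded = physchem.fusion_rate(l1, l2, ENV, FORM, IP, 1e9)
        assert k_loaded > k_empty

    def test_stale_cache_detected(self):
        pi, pj = self._pair()
        with pytest.raises(StaleCacheError):
            physchem.fusion_rate(pi, pj, ENV.evolve(csalt=0.15), FORM, IP, 1e9)


class TestBarrierScaling:
    """Equal-size barrier growth: PEG ~ R^2, DLVO electrostatic ~ R."""

    def test_peg_exponent(self):
        r = np.geomspace(5, 40, 12)
        e = physchem.pair_peg_barrier(r, r, 0.02, 0.02, 3.6, 1.3, 0.2)
        slope = np.polyfit(np.log(r), np.log(e), 1)[0]
        assert slope == pytest.approx(2.0, abs=0.05)

    def test_dlvo_exponent(self):
        ip0 = InteractionParams(hamaker=0.0)
        r = np.geomspace(5, 40, 12)
        e = physchem.dlvo_barrier_arrays(r, r, np.full_like(r, 2.0),
                                         np.full_like(r, 2.0), ENV, ip0)
        slope = np.polyfit(np.log(r), np.log(e), 1)[0]
        assert slope == pytest.approx(1.0, abs=0.05)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(
    ri=st.floats(2.0, 50.0),
    rj=st.floats(2.0, 50.0),
    pi=st.floats(-4.0, 4.0),
    pj=st.floats(-4.0, 4.0),
    phi_i=st.floats(0.0, 0.1),
    phi_j=st.floats(0.0, 0.1),
)
def test_pair_functions_symmetric(ri, rj, pi, pj, phi_i, phi_j):
    """All pair quantities are invariant under swapping the two particles."""
    k1 = physchem.collision_rate(ri, rj, ENV)
    k2 = physchem.collision_rate(rj, ri, ENV)
    assert k1 == pytest.approx(k2, rel=1e-12)
    e1 = physchem.pair_peg_barrier(ri, rj, phi_i, phi_j, 3.6, 1.3, 0.2)
    e2 = physchem.pair_peg_barrier(rj, ri, phi_j, phi_i, 3.6, 1.3, 0.2)
    assert e1 == pytest.approx(e2, rel=1e-12)
    w1 = physchem.dlvo_energy(1.0, ri, rj, ENV, IP, psi_i=pi, psi_j=pj)
    w2 = physchem.dlvo_energy(1.0, rj, ri, ENV, IP, psi_i=pj, psi_j=pi)
    assert w1 == pytest.approx(w2, rel=1e-12, abs=1e-15)
    r1 = physchem.pair_rate(np.atleast_1d(ri), np.atleast_1d(rj), phi_i, phi_j,
                            pi, pj, FORM, ENV, IP, 1e9)
    r2 = physchem.pair_rate(np.atleast_1d(rj), np.atleast_1d(ri), phi_j, phi_i,
                            pj, pi, FORM, ENV, IP, 1e9)
    assert r1[0] == pytest.approx(r2[0], rel=1e-9)
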