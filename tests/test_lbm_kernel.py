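"""Lattice descriptors and single-step kernel operators."""

import math

import numpy as np
import pytest

from coaflow.lbm import (D2Q9, D3Q19, UnitMap, channel_2d,
                         inclined_channel_2d, straight_tube)
from coaflow.lbm.kernel import (collide_smagorinsky, equilibrium, moments,
                                outlet_split, smagorinsky_tau, smooth_startup,
                                stream)
from coaflow.lbm.wall import wall_stress, y_plus
from coaflow.lbm.benchmarks import bouzidi_equals_bounceback


@pytest.mark.parametrize("desc_factory", [D2Q9, D3Q19])
class TestDescriptor:
    def test_weights_and_velocities(self, desc_factory):
        desc = desc_factory()
        assert desc.w.sum() == pytest.approx(1.0)
        assert np.allclose(desc.w @ desc.c, 0.0)

    def test_opposite_map_is_involution(self, desc_factory):
        desc = desc_factory()
        assert np.array_equal(desc.opp[desc.opp], np.arange(desc.q))
        assert np.array_equal(desc.c[desc.opp], -desc.c)


class TestEquilibrium:
    def test_rest_state_gives_weights(self):
        desc = D3Q19()
        rho = np.ones((3, 3, 3))
        u = np.zeros((3, 3, 3, 3))
        feq = equilibrium(rho, u, desc)
        assert feq[0, 1, 1, 1] == pytest.approx(1.0 / 3.0)
        for a in range(desc.q):
            assert np.allclose(feq[a], desc.w[a])

    def test_moments_reproduced_exactly(self):
        desc = D2Q9()
        rng = np.random.default_rng(2)
        rho = 1.0 + 0.1 * rng.random((4, 5))
        u = 0.05 * (rng.random((4, 5, 2)) - 0.5)
        feq = equilibrium(rho, u, desc)
        rho2, u2 = moments(feq, desc)
        assert np.allclose(rho2, rho, atol=1e-14)
        assert np.allclose(u2, u, atol=1e-14)


class TestStream:
    def test_single_population_moves_one_cell(self):
        desc = D2Q9()
        f = np.zeros((desc.q, 5, 5))
        f[1, 2, 2] = 1.0  # direction (1, 0)
        out = stream(f, desc=desc)
        assert out[1, 3, 2] == 1.0
        assert out.sum() == 1.0

    def test_mass_conserved_periodic(self):
        desc = D3Q19()
        rng = np.random.default_rng(3)
        f = rng.random((desc.q, 4, 4, 4))
        assert stream(f, desc=desc).sum() == pytest.approx(f.sum())

    def test_two_steps_compose_to_distance_two(self):
        desc = D2Q9()
        rng = np.random.default_rng(4)
        f = rng.random((desc.q, 6, 7))
        twice = stream(stream(f, desc=desc), desc=desc)
        for a in range(desc.q):
            direct = np.roll(f[a], shift=tuple(2 * desc.c[a]), axis=(0, 1))
            assert np.array_equal(twice[a], direct)


class TestCollision:
    def test_equilibrium_is_fixed_point(self):
        desc = D2Q9()
        rho = np.ones((4, 4))
        u = np.full((4, 4, 2), 0.02)
        feq = equilibrium(rho, u, desc)
        out = collide_smagorinsky(feq, desc, nu0_lattice=0.05, c_smag=0.1)
        assert np.allclose(out, feq, atol=1e-14)

    def test_zero_cs_reduces_to_plain_bgk(self):
        desc = D2Q9()
        rng = np.random.default_rng(5)
        f = equilibrium(1 + 0.05 * rng.random((4, 4)),
                        0.03 * (rng.random((4, 4, 2)) - 0.5), desc)
        f += 1e-4 * rng.random(f.shape)
        tau0 = 3 * 0.05 + 0.5
        rho, u = moments(f, desc)
        feq = equilibrium(rho, u, desc)
        expected = f - (f - feq) / tau0
        out = collide_smagorinsky(f, desc, 0.05, c_smag=0.0)
        assert np.array_equal(out, expected)

    def test_tau_eff_quadratic_closure_oracle(self):
        # tau^2 - tau0 tau - 18 Cs^2 |Pi|/rho = 0, positive root
        tau0, pi_mag, rho, cs = 0.65, 2.5e-4, 1.0, 0.1
        expected = 0.5 * (tau0 + math.sqrt(tau0**2 + 18 * cs**2 * pi_mag / rho))
        assert smagorinsky_tau(tau0, np.array(pi_mag), np.array(rho), cs) \
            == pytest.approx(expected)

    def test_unstable_tau_rejected(self):
        desc = D2Q9()
        f = equilibrium(np.ones((3, 3)), np.zeros((3, 3, 2)), desc)
        with pytest.raises(Exception):
            collide_smagorinsky(f, desc, nu0_lattice=0.0, c_smag=0.0)


class TestBouzidi:
    def test_branch_continuity_at_half(self):
        # q -> 1/2 from either side gives plain bounce-back
        fa, fe, fb = 0.7, 0.4, 0.9
        low = 2 * 0.5 * fa + (1 - 2 * 0.5) * fe
        high = fa / (2 * 0.5) + (2 * 0.5 - 1) / (2 * 0.5) * fb
        assert low == pytest.approx(high) == pytest.approx(fa)

    def test_equals_bounceback_at_q_half_bitwise(self):
        assert bouzidi_equals_bounceback(n_steps=30)["max_abs_difference"] == 0.0

    def test_inclined_wall_has_subcell_fractions(self):
        grid = inclined_channel_2d(24, 24, D2Q9(), angle_deg=12.0)
        qs = np.concatenate([r["q"] for r in grid.wall_links.values()])
        assert qs.min() < 0.35 and qs.max() > 0.65  # genuinely sub-cell


class TestInletAndOutlet:
    def test_outlet_split_proportional(self):
        np.testing.assert_allclose(outlet_split(10.0, [1.0, 2.0, 3.0]),
                                   [10 / 6, 20 / 6, 30 / 6])
        q = outlet_split(7.3, [2.0, 2.0])
        assert q[0] == q[1]
        assert outlet_split(5.0, [1, 2, 3]).sum() == pytest.approx(5.0)

    def test_outlet_split_empty_rejected(self):
        with pytest.raises(ValueError):
            outlet_split(1.0, [])

    def test_smooth_startup_continuity_and_slope(self):
        wave = lambda t: 2.0 + math.sin(t)
        ramped = smooth_startup(wave, t_ramp=0.5)
        assert ramped(0.0) == 0.0
        assert ramped(0.5) == pytest.approx(wave(0.0))
        ts = np.linspace(0, 0.5, 2001)
        du = np.gradient([ramped(t) for t in ts], ts)
        assert du.max() == pytest.approx(math.pi / 2 * wave(0.0) / 0.5, rel=1e-3)


class TestWallStress:
    def test_zero_flow_zero_shear(self):
        desc = D2Q9()
        grid = channel_2d(4, 16, desc)
        f = equilibrium(np.ones(grid.shape), np.zeros(grid.shape + (2,)), desc)
        um = UnitMap(dx=1.0, nu_phys=0.05, nu_lattice=0.05, rho_phys=1.0)
        samples = wall_stress(f, grid, 0.05, um)
        assert samples.shear_mag.max() < 1e-10

    def test_traction_orthogonal_to_normal(self):
        desc = D3Q19()
        grid = straight_tube(4, 5.5, desc)
        rng = np.random.default_rng(6)
        rho = np.ones(grid.shape)
        u = 0.03 * rng.random(grid.shape + (3,))
        u[~grid.fluid_mask] = 0.0
        f = equilibrium(rho, u, desc) \
            + 1e-5 * rng.random((desc.q,) + grid.shape)
        um = UnitMap(dx=1.0, nu_phys=0.05, nu_lattice=0.05, rho_phys=1.0)
        samples = wall_stress(f, grid, 0.05, um)
        dots = np.einsum("ni,ni->n", samples.traction, samples.normals)
        assert np.abs(dots).max() < 1e-10 * max(samples.shear_mag.max(), 1.0)


class TestYPlus:
    def test_zero_shear(self):
        assert y_plus(0.0, 1e-4, 3.33e-6) == 0.0

    def test_hand_case(self):
        # y=1e-4 m, tau_w=1 Pa, rho=1050, nu=3.33e-6:
        # u_tau = sqrt(1/1050) = 0.030861 -> y+ = 0.92675
        assert y_plus(1.0, 1e-4, 3.33e-6, 1050.0) == pytest.approx(
            0.926747, rel=1e-4)

    def test_linear_in_distance(self):
        assert y_plus(1.0, 2e-4, 3.33e-6) == pytest.approx(
            2 * y_plus(1.0, 1e-4, 3.33e-6))


class TestUnitMap:
    def test_diffusive_scaling_identity(self):
        um = UnitMap(dx=1e-3, nu_phys=3.33e-6, nu_lattice=0.05)
        assert um.dt == pytest.approx(um.nu_lattice / um.nu_phys * um.dx**2)

    def test_tau_bounds_respected(self):
        um = UnitMap.for_velocity(dx=5e-4, u_phys_max=1.5)
        assert 0.51 <= um.tau0 <= 0.8
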