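"""Elastic energies, analytic gradients, minimization and shear response."""

import numpy as np
import pytest

from fiberplast import (
    BoundarySpec,
    ElasticParams,
    apply_shear,
    bending_energy,
    build_triangular_lattice,
    differential_shear_modulus,
    dilute,
    energy_breakdown,
    minimize,
    shear_strain,
    stretching_energy,
    total_energy_and_gradient,
)
from fiberplast.fixtures import make_toy_network, state_from_arrays


class TestStretching:
    def test_single_bond_closed_form(self, elastic):
        state = make_toy_network("single_bond")
        state.positions[1, 0] = 1.1
        assert stretching_energy(state, elastic) == pytest.approx(0.005)

    def test_undeformed_zero(self, elastic, small_diluted):
        assert stretching_energy(small_diluted, elastic) == pytest.approx(0.0, abs=1e-20)

    def test_matches_per_bond_hand_sum(self, elastic, rng):
        state = dilute(build_triangular_lattice(4, 4), 0.8, seed=9)
        state.positions += 0.05 * rng.standard_normal(state.positions.shape)
        expected = 0.0
        for (i, j), l0, s in zip(
            state.bonds, state.rest_lengths, state.bond_shifts
        ):
            l = np.linalg.norm(state.positions[j] + s - state.positions[i])
            expected += elastic.k / (2 * l0) * (l - l0) ** 2
        assert stretching_energy(state, elastic) == pytest.approx(expected)

    def test_unnormalized_variant(self):
        params = ElasticParams(normalize_stretch=False)
        state = make_toy_network("single_bond")
        state.rest_lengths[:] = 2.0
        state.positions[1, 0] = 2.2
        # plain Hookean: k/2 (l - l0)^2, no 1/l0
        assert stretching_energy(state, params) == pytest.approx(0.5 * 0.04)


class TestBending:
    def test_straight_fiber_zero(self, elastic):
        state = make_toy_network("straight_fiber_3")
        assert bending_energy(state, elastic) == 0.0

    def test_two_bond_hinge_closed_form(self, elastic):
        th = 0.1
        pos = [[0, 0], [1, 0], [1 + np.cos(th), np.sin(th)]]
        state = state_from_arrays(pos, [[0, 1], [1, 2]])
        state.fiber_id[:] = 0  # one fiber despite the kink
        state.invalidate_topology()
        assert bending_energy(state, elastic) == pytest.approx(
            0.5 * 1e-3 * th**2
        )

    def test_zigzag_sums_hinges(self, elastic):
        t1, t2 = 0.2, -0.3
        p0 = np.array([0.0, 0.0])
        p1 = p0 + [1, 0]
        p2 = p1 + [np.cos(t1), np.sin(t1)]
        p3 = p2 + [np.cos(t1 + t2), np.sin(t1 + t2)]
        state = state_from_arrays([p0, p1, p2, p3], [[0, 1], [1, 2], [2, 3]])
        state.fiber_id[:] = 0
        state.invalidate_topology()
        expected = 0.5 * 1e-3 * (t1**2 + t2**2)
        assert bending_energy(state, elastic) == pytest.approx(expected)

    def test_no_coupling_across_fibers(self, elastic):
        state = make_toy_network("x_junction")
        # rotate one fiber's arm: bending couples only within a fiber, and
        # both fibers stay straight, so bending energy remains zero only if
        # the kink is within a fiber
        state.positions[2] = [np.cos(0.3) + 0, np.sin(0.3)]
        assert bending_energy(state, elastic) > 0
        # but kinking fiber B relative to fiber A at the shared node adds
        # nothing beyond B's own hinge terms
        eb = bending_energy(state, elastic)
        hinges = state.hinges()
        assert len(hinges[0]) == 2  # one hinge per 2-bond fiber


class TestGradient:
    def test_equilibrium_gradient_zero(self, elastic, small_diluted):
        _, grad = total_energy_and_gradient(small_diluted, elastic)
        assert np.max(np.abs(grad)) < 1e-12

    def test_matches_finite_differences(self, elastic):
        rng = np.random.default_rng(7)
        for trial in range(3):
            state = dilute(build_triangular_lattice(5, 5), 0.7, seed=trial)
            state.positions += 0.05 * rng.standard_normal(state.positions.shape)
            _, grad = total_energy_and_gradient(state, elastic)
            h = 1e-6
            for n in rng.choice(state.n_nodes, 6, replace=False):
                for c in (0, 1):
                    orig = state.positions[n, c]
                    state.positions[n, c] = orig + h
                    ep = stretching_energy(state, elastic) + bending_energy(state, elastic)
                    state.positions[n, c] = orig - h
                    em = stretching_energy(state, elastic) + bending_energy(state, elastic)
                    state.positions[n, c] = orig
                    fd = (ep - em) / (2 * h)
                    denom = max(1e-8, abs(fd) + abs(grad[n, c]))
                    assert abs(fd - grad[n, c]) / denom < 1e-5

    def test_single_stretched_bond_hooke(self, elastic):
        state = make_toy_network("single_bond")
        state.positions[1, 0] = 1.1
        _, grad = total_energy_and_gradient(state, elastic)
        # dE/dx of the far node is +k (l - l0) = 0.1; reaction on the other
        assert grad[1, 0] == pytest.approx(0.1)
        assert grad[0, 0] == pytest.approx(-0.1)


class TestMinimize:
    def test_undeformed_unchanged(self, elastic, small_diluted):
        res = minimize(small_diluted, elastic)
        assert res.energy.total == pytest.approx(0.0, abs=1e-14)
        assert np.allclose(res.state.positions, small_diluted.positions)

    def test_energy_descends_from_prestretch(self, elastic, bulk_boundary):
        state = dilute(build_triangular_lattice(8, 8, bulk_boundary), 1.0, seed=0)
        state.positions *= 1.05  # uniform prestretch, edges pinned after scaling
        e0 = stretching_energy(state, elastic)
        res = minimize(state, elastic)
        assert res.energy.total < e0
        assert res.converged

    def test_deterministic(self, elastic, bulk_boundary):
        def run():
            state = dilute(build_triangular_lattice(8, 8, bulk_boundary), 0.7, seed=5)
            apply_shear(state, 0.1)
            return minimize(state, elastic).state.positions

        assert np.array_equal(run(), run())

    def test_rigid_rotation_leaves_energy_unchanged(self, elastic):
        state = dilute(build_triangular_lattice(6, 6), 0.7, seed=2)
        state.positions += 0.02 * np.random.default_rng(0).standard_normal(
            state.positions.shape
        )
        e0 = stretching_energy(state, elastic) + bending_energy(state, elastic)
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        state.positions = state.positions @ rot.T
        e1 = stretching_energy(state, elastic) + bending_energy(state, elastic)
        assert e1 == pytest.approx(e0, rel=1e-10)


class TestShear:
    def test_zero_shear_identity(self, elastic, bulk_boundary):
        state = dilute(build_triangular_lattice(8, 8, bulk_boundary), 0.7, seed=1)
        before = state.positions.copy()
        apply_shear(state, 0.0)
        assert np.array_equal(state.positions, before)

    def test_pinned_boundary_sets_strain(self, elastic, bulk_boundary):
        state = dilute(build_triangular_lattice(10, 10, bulk_boundary), 0.7, seed=1)
        apply_shear(state, 0.2)
        res = minimize(state, elastic, in_place=True, warn=False)
        assert shear_strain(res.state) == pytest.approx(0.2)

    def test_energy_even_in_gamma_for_mirrored_network(self, elastic, bulk_boundary):
        """E(gamma) of a network equals E(-gamma) of its x-mirror image."""
        geom = build_triangular_lattice(8, 8, bulk_boundary)
        state = dilute(geom, 0.7, seed=4)
        mirror = state.copy()
        x_max = mirror.positions[:, 0].max() + mirror.positions[:, 0].min()
        mirror.positions[:, 0] = x_max - mirror.positions[:, 0]
        mirror.bond_shifts[:, 0] *= -1
        for st, g in ((state, 0.08), (mirror, -0.08)):
            apply_shear(st, g)
        e1 = minimize(state, elastic, warn=False).energy.total
        e2 = minimize(mirror, elastic, warn=False).energy.total
        assert e1 == pytest.approx(e2, rel=1e-5)


class TestModulus:
    def test_affine_closed_form_oracle(self, bulk_boundary):
        """Fully pinned 2-row strip: all nodes on fixed rows, so shear is
        exactly affine and the energy has a closed form."""
        params = ElasticParams(kappa=0.0)
        state = dilute(build_triangular_lattice(4, 2, bulk_boundary), 1.0, seed=0)

        def affine_energy(g):
            st = state.copy()
            apply_shear(st, g)
            return stretching_energy(st, params)

        d = 1e-3
        g0 = 0.1
        area = state.geometry.width * state.geometry.height
        expected = (
            affine_energy(g0 + d) - 2 * affine_energy(g0) + affine_energy(g0 - d)
        ) / (d * d * area)
        st = state.copy()
        apply_shear(st, g0)
        st = minimize(st, params, in_place=True, warn=False).state
        got = differential_shear_modulus(st, params, g0, d)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_full_lattice_rigid_at_zero_strain(self, bulk_boundary):
        """p = 1 with central forces only is above isostaticity: G(0) > 0."""
        params = ElasticParams(kappa=0.0)
        state = dilute(build_triangular_lattice(10, 10, bulk_boundary), 1.0, seed=0)
        state = minimize(state, params, in_place=True, warn=False).state
        g = differential_shear_modulus(state, params, 0.0)
        assert g > 0.1

    def test_linear_regime_bending_dominated(self, elastic, bulk_boundary):
        """At p = 0.60 and 2% shear the diluted network's elastic energy is
        mostly bending; deep shear is stretching-dominated."""
        state = dilute(build_triangular_lattice(20, 20, bulk_boundary), 0.6, seed=3)
        small = state.copy()
        apply_shear(small, 0.02)
        bd_small = minimize(small, elastic, in_place=True, warn=False).energy
        assert bd_small.bend > bd_small.stretch
        apply_shear(state, 0.3)
        bd_big = minimize(state, elastic, in_place=True, warn=False).energy
        assert bd_big.stretch > bd_big.bend


class TestBreakdown:
    def test_per_fiber_bend_density(self, elastic):
        state = make_toy_network("straight_fiber_3")
        th = 0.15
        state.positions[3] = state.positions[2] + [np.cos(th), np.sin(th)]
        bd = energy_breakdown(state, elastic)
        assert bd.total == pytest.approx(bd.stretch + bd.bend)
        fid = int(state.fiber_id[0])
        # one kinked hinge on a fiber of rest length 3
        assert bd.per_fiber_bend_density[fid] == pytest.approx(
            0.5 * 1e-3 * th**2 / 3.0
        )
        assert bd.mean_energy_per_fiber == pytest.approx(bd.total)
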