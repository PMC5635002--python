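"""Bundle metrics, nematic order, relaxation fits, compliance probing."""

import numpy as np
import pytest

from fiberplast import ElasticParams, build_triangular_lattice, dilute
from fiberplast.analysis import (
    bundle_density_ratio,
    fit_double_exponential,
    fit_single_exponential,
    nematic_order,
    probe_compliance,
)
from fiberplast.fixtures import make_synthetic_relaxation, state_from_arrays
from fiberplast.protocols import CellSpec


def _two_cells(center, d, radius=1.5, beta=0.3):
    return [
        CellSpec(center=(center[0] - d / 2, center[1]), radius=radius, beta=beta),
        CellSpec(center=(center[0] + d / 2, center[1]), radius=radius, beta=beta),
    ]


class TestBundleDensity:
    def test_uniform_network_near_zero(self):
        state = dilute(build_triangular_lattice(20, 20), 0.7, seed=1)
        center = state.positions.mean(axis=0)
        m = bundle_density_ratio(state, _two_cells(center, 8.0))
        assert abs(m.delta_F_over_F) < 0.25  # counting noise only

    def test_hand_built_toy_matches_manual_count(self):
        """A row of bonds between the cells vs a sparse background with
        hand-countable areas."""
        # cells at (0,0) and (6,0), radius 1 -> ROB: x in [1,5], |y| <= 1
        # (width = 2 = cell diameter), area 8.
        pos, bonds = [], []
        for kx in range(5):  # 5 bonds of length 0.8 inside the ROB
            x = 1.2 + 0.8 * kx * 0.9
            pos += [[x, 0.0], [x + 0.8, 0.0]]
            bonds.append([2 * kx, 2 * kx + 1])
        n0 = len(pos)
        for kx in range(4):  # background bonds far away
            x = -8 + 4 * kx
            pos += [[x, 6.0], [x + 1.0, 6.0]]
            bonds.append([n0 + 2 * kx, n0 + 2 * kx + 1])
        # corner markers pin the convex hull to a known rectangle
        pos += [[-10, -8], [10, -8], [-10, 8], [10, 8]]
        state = state_from_arrays(pos, bonds)
        cells = [
            CellSpec(center=(0.0, 0.0), radius=1.0, beta=0.1),
            CellSpec(center=(6.0, 0.0), radius=1.0, beta=0.1),
        ]
        m = bundle_density_ratio(state, cells, domain="hull")
        rob_area = 4.0 * 2.0
        domain_area = 20.0 * 16.0
        bg_area = domain_area - rob_area - 2 * np.pi
        f_b = 5 / rob_area
        f_bg = 4 / bg_area
        assert m.F_bundle == pytest.approx(f_b)
        assert m.F_background == pytest.approx(f_bg)
        assert m.delta_F_over_F == pytest.approx((f_b - f_bg) / f_bg)

    def test_invariant_under_rigid_translation(self):
        state = dilute(build_triangular_lattice(16, 16), 0.7, seed=2)
        center = state.positions.mean(axis=0)
        cells = _two_cells(center, 7.0)
        m0 = bundle_density_ratio(state, cells)
        shift = np.array([3.7, -1.9])
        moved = state.copy()
        moved.positions = moved.positions + shift
        cells_moved = [
            CellSpec(
                center=(c.center[0] + shift[0], c.center[1] + shift[1]),
                radius=c.radius,
                beta=c.beta,
            )
            for c in cells
        ]
        m1 = bundle_density_ratio(moved, cells_moved)
        assert m1.delta_F_over_F == pytest.approx(m0.delta_F_over_F, rel=1e-9)

    def test_touching_cells_rejected(self):
        state = dilute(build_triangular_lattice(12, 12), 0.7, seed=0)
        center = state.positions.mean(axis=0)
        cells = _two_cells(center, 2.9, radius=1.5)
        with pytest.raises(ValueError):
            bundle_density_ratio(state, cells)


class TestNematicOrder:
    def test_parallel_bonds_unity(self):
        pos = [[0, 0], [1, 0], [0, 1], [1, 1], [0, 2], [1, 2]]
        state = state_from_arrays(pos, [[0, 1], [2, 3], [4, 5]])
        assert nematic_order(state) == pytest.approx(1.0)

    def test_single_bond_unity(self):
        state = state_from_arrays([[0, 0], [0.3, 0.9]], [[0, 1]])
        assert nematic_order(state) == pytest.approx(1.0)

    def test_three_lattice_directions_cancel(self):
        """Equal weight along 0, 60 and 120 degrees: <cos 2 theta> = 0."""
        s3 = np.sqrt(3) / 2
        pos = [[0, 0], [1, 0], [3, 0], [3.5, s3], [6, 0], [5.5, s3]]
        state = state_from_arrays(pos, [[0, 1], [2, 3], [4, 5]])
        assert nematic_order(state) == pytest.approx(0.0, abs=1e-12)

    def test_empty_region_raises(self):
        state = state_from_arrays([[0, 0], [1, 0]], [[0, 1]])
        with pytest.raises(ValueError):
            nematic_order(state, region=np.array([False]))


class TestSingleExponentialFit:
    def test_noiseless_recovery_machine_precision(self):
        t = np.arange(0, 30, 0.5)
        y = 0.1 * np.exp(-t / 1.0) + 0.05  # tau = 60 s in minutes
        fit = fit_single_exponential(t, y)
        assert fit.amplitude == pytest.approx(0.1, abs=1e-8)
        assert fit.tau == pytest.approx(1.0, abs=1e-8)
        assert fit.offset == pytest.approx(0.05, abs=1e-8)

    def test_constant_series(self):
        t = np.arange(0, 10, 0.5)
        fit = fit_single_exponential(t, np.full_like(t, 0.07))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-10)
        assert fit.offset == pytest.approx(0.07)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_single_exponential(np.array([0, 1, 2]), np.array([1, 0.5, 0.2]))

    def test_monte_carlo_tau_bias_small(self):
        """2%-of-amplitude noise: tau recovered with < 5% bias over seeds."""
        t = np.arange(0, 20, 0.25)
        taus = []
        for seed in range(30):
            rng = np.random.default_rng(seed)
            y = 0.1 * np.exp(-t / 2.0) + 0.05 + 0.002 * rng.standard_normal(t.size)
            taus.append(fit_single_exponential(t, y).tau)
        assert abs(np.mean(taus) - 2.0) / 2.0 < 0.05


class TestDoubleExponentialFit:
    def test_noiseless_exact_recovery(self):
        s = make_synthetic_relaxation(
            a=0.06, tau_v_s=30, b=0.09, tau_p_min=6.0, eps_r=0.04,
            noise_sigma=0.0, dt_s=15, t_end_min=25,
        )
        fit = fit_double_exponential([s])
        assert float(np.atleast_1d(fit.tau_v)[0]) == pytest.approx(0.5, rel=1e-6)
        assert fit.tau_p[0] == pytest.approx(6.0, rel=1e-6)
        assert fit.eps_r[0] == pytest.approx(0.04, abs=1e-8)
        assert fit.a[0] == pytest.approx(0.06, abs=1e-7)
        assert fit.b[0] == pytest.approx(0.09, abs=1e-7)

    def test_joint_shared_tau_v_recovery_with_noise(self):
        series = [
            make_synthetic_relaxation(
                a=0.05, tau_v_s=30, b=0.1, tau_p_min=tp, eps_r=0.03,
                noise_sigma=0.0015, dt_s=15, t_end_min=25, seed=100 + k,
            )
            for k, tp in enumerate([2, 5, 9, 14, 20])
        ]
        fit = fit_double_exponential(series, shared_tau_v=True)
        assert fit.tau_v_seconds == pytest.approx(30.0, rel=0.05)
        for got, true in zip(fit.tau_p, [2, 5, 9, 14, 20]):
            assert got == pytest.approx(true, rel=0.10)

    def test_single_exponential_input_degenerates_gracefully(self):
        s = make_synthetic_relaxation(
            a=0.0, tau_v_s=30, b=0.1, tau_p_min=5.0, eps_r=0.05,
            noise_sigma=0.0, dt_s=30, t_end_min=20,
        )
        fit = fit_double_exponential([s])
        # one branch must vanish (the fit collapses to a single
        # exponential) or the fit must flag weak identifiability
        assert abs(fit.b[0]) < 1e-4 or abs(fit.a[0]) < 1e-4 or fit.flagged

    def test_per_series_mode(self):
        series = [
            make_synthetic_relaxation(
                a=0.05, tau_v_s=tv, b=0.1, tau_p_min=8.0, eps_r=0.03,
                noise_sigma=0.0, dt_s=15, t_end_min=25,
            )
            for tv in (20, 40)
        ]
        fit = fit_double_exponential(series, shared_tau_v=False)
        assert np.asarray(fit.tau_v).shape == (2,)
        assert fit.tau_v_seconds[0] == pytest.approx(20, rel=1e-4)
        assert fit.tau_v_seconds[1] == pytest.approx(40, rel=1e-4)


class TestComplianceProbe:
    def test_full_lattice_isotropic(self, elastic):
        """Six-fold symmetry of the undiluted lattice implies an isotropic
        linear response: aspect ratio ~ 1."""
        state = dilute(build_triangular_lattice(13, 13), 1.0, seed=0)
        center = int(
            np.argmin(
                np.linalg.norm(
                    state.positions - state.positions.mean(axis=0), axis=1
                )
            )
        )
        # clamp everything outside a disk centered on the probe node: the
        # free region then has the exact six-fold symmetry of the lattice
        r = np.linalg.norm(state.positions - state.positions[center], axis=1)
        state.free = r < 4.2
        probe = probe_compliance(state, elastic, center)
        assert not probe.flagged
        assert probe.aspect_ratio == pytest.approx(1.0, abs=0.02)

    def test_linear_response_symmetric_under_force_reversal(self, elastic):
        state = dilute(build_triangular_lattice(10, 10), 0.8, seed=5)
        edge = (
            (state.positions[:, 1] < 0.5)
            | (state.positions[:, 1] > state.positions[:, 1].max() - 0.5)
        )
        state.free = ~edge
        node = int(
            np.argmin(
                np.linalg.norm(
                    state.positions - state.positions.mean(axis=0), axis=1
                )
            )
        )
        probe = probe_compliance(state, elastic, node)
        n = probe.J.size
        for k in range(n // 2):
            assert probe.J[k] == pytest.approx(probe.J[k + n // 2], rel=0.05, abs=1e-3)

    def test_fixed_node_rejected(self, elastic):
        state = dilute(build_triangular_lattice(6, 6), 1.0, seed=0)
        state.free[3] = False
        with pytest.raises(ValueError):
            probe_compliance(state, elastic, 3)
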