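"""Deterministic toy networks and synthetic relaxation curves.

Every fixture is generated programmatically from a name (and seed where
randomness is involved), so tests and demos never need external data.
"""

from __future__ import annotations

import numpy as np

from .analysis import RelaxationSeries
from .lattice import (
    A0,
    BoundarySpec,
    NetworkGeometry,
    NetworkState,
    build_triangular_lattice,
    dilute,
    identify_fibers,
)

__all__ = ["TOY_NETWORKS", "make_toy_network", "make_synthetic_relaxation", "state_from_arrays"]

_SQ3 = np.sqrt(3.0) / 2.0

TOY_NETWORKS = (
    "single_bond",
    "straight_fiber_3",
    "x_junction",
    "t_branch",
    "mini_lattice_5x5",
    "two_cell_12x12",
)


def state_from_arrays(
    positions: np.ndarray,
    bonds: np.ndarray,
    rest_lengths: np.ndarray | None = None,
    free: np.ndarray | None = None,
) -> NetworkState:
    """Assemble a hand-built network; fibers identified by collinearity."""
    positions = np.asarray(positions, dtype=float)
    bonds = np.asarray(bonds, dtype=np.int64)
    n, m = positions.shape[0], bonds.shape[0]
    geom = NetworkGeometry(
        node_positions=positions.copy(),
        lattice_dims=(max(n, 2), 2),
        boundary_spec=BoundarySpec(),
        candidate_bonds=bonds.copy(),
        candidate_shifts=np.zeros((m, 2)),
        candidate_dirs=np.zeros(m, dtype=np.int64),
    )
    if rest_lengths is None:
        d = positions[bonds[:, 1]] - positions[bonds[:, 0]]
        rest_lengths = np.linalg.norm(d, axis=1)
    state = NetworkState(
        geometry=geom,
        positions=positions.copy(),
        bonds=bonds.copy(),
        rest_lengths=np.asarray(rest_lengths, dtype=float).copy(),
        bond_shifts=np.zeros((m, 2)),
        fiber_id=np.zeros(m, dtype=np.int64),
        merged=np.zeros(m, dtype=bool),
        free=np.ones(n, dtype=bool) if free is None else np.asarray(free, bool),
    )
    return identify_fibers(state)


def make_toy_network(name: str, seed: int = 0) -> NetworkState:
    """Return one of the documented hand-checkable toy geometries.

    ``single_bond``: 2 nodes, 1 unit bond.
    ``straight_fiber_3``: 3 collinear unit bonds, one fiber.
    ``x_junction``: two 2-bond fibers crossing at a shared center node.
    ``t_branch``: a 2-bond through fiber plus a 1-bond branch ending on it.
    ``mini_lattice_5x5``: seeded dilution (p = 0.7) of a 5x5 lattice.
    ``two_cell_12x12``: seeded 12x12 dilution with two embedded cells.
    """
    if name == "single_bond":
        return state_from_arrays([[0.0, 0.0], [1.0, 0.0]], [[0, 1]])
    if name == "straight_fiber_3":
        pos = [[0.0, 0.0], [1.0, 0.0], [2.0, 0.0], [3.0, 0.0]]
        return state_from_arrays(pos, [[0, 1], [1, 2], [2, 3]])
    if name == "x_junction":
        pos = [
            [-1.0, 0.0], [0.0, 0.0], [1.0, 0.0],  # fiber along x
            [-0.5, -_SQ3], [0.5, _SQ3],  # fiber along the 60-degree axis
        ]
        return state_from_arrays(pos, [[0, 1], [1, 2], [3, 1], [1, 4]])
    if name == "t_branch":
        pos = [[-1.0, 0.0], [0.0, 0.0], [1.0, 0.0], [0.5, _SQ3]]
        return state_from_arrays(pos, [[0, 1], [1, 2], [1, 3]])
    if name == "mini_lattice_5x5":
        return dilute(build_triangular_lattice(5, 5), 0.7, seed)
    if name == "two_cell_12x12":
        from .protocols import CellSpec, embed_cells

        state = dilute(build_triangular_lattice(12, 12), 0.7, seed)
        center = state.positions.mean(axis=0)
        cells = [
            CellSpec(center=(center[0] - 2.5, center[1]), radius=1.5, beta=0.3),
            CellSpec(center=(center[0] + 2.5, center[1]), radius=1.5, beta=0.3),
        ]
        return embed_cells(state, cells)
    raise ValueError(f"unknown toy network {name!r}; choose from {TOY_NETWORKS}")


def make_synthetic_relaxation(
    a: float = 0.05,
    tau_v_s: float = 30.0,
    b: float = 0.1,
    tau_p_min: float = 8.0,
    eps_r: float = 0.05,
    noise_sigma: float = 0.0,
    dt_s: float = 30.0,
    t_end_min: float = 30.0,
    seed: int = 0,
) -> RelaxationSeries:
    """Sample a noisy double-exponential strain-relaxation curve.

    ``eps(t) = a exp(-t/tau_v) + b exp(-t/tau_p) + eps_r`` with i.i.d.
    Gaussian noise of standard deviation ``noise_sigma``.  Defaults mirror
    the scales of sheared collagen gels: a fast ~30 s viscoelastic-like
    mode well separated from a plastic mode of minutes, relaxing from 20%
    strain toward a finite residual.
    """
    if tau_v_s <= 0 or tau_p_min <= 0:
        raise ValueError("time constants must be positive")
    if noise_sigma < 0:
        raise ValueError("noise_sigma must be >= 0")
    t = np.arange(0.0, t_end_min + 1e-9, dt_s / 60.0)
    tau_v_min = tau_v_s / 60.0
    eps = a * np.exp(-t / tau_v_min) + b * np.exp(-t / tau_p_min) + eps_r
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        eps = eps + noise_sigma * rng.standard_normal(t.shape)
    return RelaxationSeries(
        t=t,
        strain=eps,
        eps0=float(a + b + eps_r),
        eps0_plus=float(a + b + eps_r),
        meta={
            "a": a, "tau_v_s": tau_v_s, "b": b, "tau_p_min": tau_p_min,
            "eps_r": eps_r, "noise_sigma": noise_sigma, "seed": seed,
        },
    )
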