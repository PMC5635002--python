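"""Quasistatic elasticity of bend/stretch fiber networks.

Energy functional
-----------------
Stretching: each bond of rest length ``l0`` contributes
``k / (2 l0) * (l - l0)^2`` (spring constant normalized by rest length, as
for an elastic rod of fixed material stiffness; set
``ElasticParams.normalize_stretch=False`` for a plain Hookean spring).

Bending: each *hinge* — a pair of consecutive bonds within one fiber —
contributes ``kappa / (2 a0) * dtheta^2`` where ``dtheta`` is the angle
between the two bond vectors (rest configuration straight).  Distinct
fibers crossing at a node are not coupled by bending.

The network is athermal and quasistatic: mechanical equilibrium is found
by direct minimization of the total energy over the free degrees of
freedom (free nodes: 2 DOF; circle-constrained nodes: 1 tangential DOF;
pinned nodes: none).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .lattice import A0, NetworkState

__all__ = [
    "ElasticParams",
    "EnergyBreakdown",
    "stretching_energy",
    "bending_energy",
    "total_energy_and_gradient",
    "energy_breakdown",
    "minimize",
    "MinimizeResult",
    "apply_shear",
    "shear_strain",
    "differential_shear_modulus",
]


@dataclass(frozen=True)
class ElasticParams:
    """Stretching stiffness ``k`` and bending stiffness ``kappa``.

    Defaults ``k = 1`` and ``kappa = 1e-3`` (lattice units) place the
    diluted network in the bending-dominated linear regime characteristic
    of sub-isostatic biopolymer gels.
    """

    k: float = 1.0
    kappa: float = 1.0e-3
    normalize_stretch: bool = True

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("stretching stiffness k must be > 0")
        if self.kappa < 0:
            raise ValueError("bending stiffness kappa must be >= 0")


@dataclass
class EnergyBreakdown:
    stretch: float
    bend: float
    per_fiber_bend_density: dict[int, float] | None = None
    mean_energy_per_fiber: float | None = None

    @property
    def total(self) -> float:
        return self.stretch + self.bend


# -- raw energy/gradient kernels ------------------------------------------

def _stretch(positions, bonds, rest, shifts, k, normalize, want_grad):
    if bonds.shape[0] == 0:
        g = np.zeros_like(positions) if want_grad else None
        return 0.0, g, None
    d = positions[bonds[:, 1]] + shifts - positions[bonds[:, 0]]
    length = np.sqrt(d[:, 0] ** 2 + d[:, 1] ** 2)
    coef = k / rest if normalize else np.full_like(rest, k)
    dl = length - rest
    per_bond = 0.5 * coef * dl * dl
    energy = float(per_bond.sum())
    grad = None
    if want_grad:
        with np.errstate(invalid="ignore", divide="ignore"):
            fmag = np.where(length > 0, coef * dl / length, 0.0)
        f = fmag[:, None] * d  # dE/dx_j
        n = positions.shape[0]
        gx = np.bincount(bonds[:, 1], f[:, 0], n) - np.bincount(
            bonds[:, 0], f[:, 0], n
        )
        gy = np.bincount(bonds[:, 1], f[:, 1], n) - np.bincount(
            bonds[:, 0], f[:, 1], n
        )
        grad = np.column_stack([gx, gy])
    return energy, grad, per_bond


def _bend(positions, hinges, kappa, want_grad, per_hinge_out=False):
    a, b, c, su, sv = hinges
    n = positions.shape[0]
    if a.shape[0] == 0 or kappa == 0.0:
        g = np.zeros((n, 2)) if want_grad else None
        return 0.0, g, np.zeros(a.shape[0])
    u = positions[b] + su - positions[a]
    v = positions[c] + sv - positions[b]
    cross = u[:, 0] * v[:, 1] - u[:, 1] * v[:, 0]
    dot = u[:, 0] * v[:, 0] + u[:, 1] * v[:, 1]
    theta = np.arctan2(cross, dot)
    per_hinge = 0.5 * (kappa / A0) * theta * theta
    energy = float(per_hinge.sum())
    grad = None
    if want_grad:
        w = (kappa / A0) * theta
        inv_u2 = 1.0 / (u[:, 0] ** 2 + u[:, 1] ** 2)
        inv_v2 = 1.0 / (v[:, 0] ** 2 + v[:, 1] ** 2)
        # dtheta/du = (u_y, -u_x)/|u|^2 ; dtheta/dv = (-v_y, v_x)/|v|^2
        gu = np.column_stack([w * u[:, 1] * inv_u2, -w * u[:, 0] * inv_u2])
        gv = np.column_stack([-w * v[:, 1] * inv_v2, w * v[:, 0] * inv_v2])
        gx = (
            -np.bincount(a, gu[:, 0], n)
            + np.bincount(b, gu[:, 0] - gv[:, 0], n)
            + np.bincount(c, gv[:, 0], n)
        )
        gy = (
            -np.bincount(a, gu[:, 1], n)
            + np.bincount(b, gu[:, 1] - gv[:, 1], n)
            + np.bincount(c, gv[:, 1], n)
        )
        grad = np.column_stack([gx, gy])
    return energy, grad, per_hinge


def stretching_energy(state: NetworkState, params: ElasticParams) -> float:
    e, _, _ = _stretch(
        state.positions,
        state.bonds,
        state.rest_lengths,
        state.bond_shifts,
        params.k,
        params.normalize_stretch,
        want_grad=False,
    )
    return e


def bending_energy(state: NetworkState, params: ElasticParams) -> float:
    e, _, _ = _bend(state.positions, state.hinges(), params.kappa, False)
    return e


def total_energy_and_gradient(
    state: NetworkState,
    params: ElasticParams,
    external_forces: np.ndarray | None = None,
) -> tuple[EnergyBreakdown, np.ndarray]:
    """Total energy and its analytic gradient over *all* node coordinates.

    The returned gradient is ``dE/dx`` per node; rows for pinned nodes are
    included (useful for reaction forces) — masking to free DOFs is the
    minimizer's job.  ``external_forces`` adds a potential ``-F . x``.
    """
    es, gs, _ = _stretch(
        state.positions,
        state.bonds,
        state.rest_lengths,
        state.bond_shifts,
        params.k,
        params.normalize_stretch,
        want_grad=True,
    )
    eb, gb, _ = _bend(state.positions, state.hinges(), params.kappa, True)
    grad = gs if gb is None else gs + gb
    if external_forces is not None:  # external work not part of the breakdown
        grad = grad - external_forces
    return EnergyBreakdown(stretch=es, bend=eb), grad


def energy_breakdown(state: NetworkState, params: ElasticParams) -> EnergyBreakdown:
    """Energy components plus per-fiber bending statistics.

    ``per_fiber_bend_density`` maps fiber id to its bending energy per unit
    fiber (rest) length, the quantity H_b used to visualize heterogeneous
    bending-energy localization; ``mean_energy_per_fiber`` is the total
    elastic energy divided by the number of fibers (<H>).
    """
    es, _, _ = _stretch(
        state.positions,
        state.bonds,
        state.rest_lengths,
        state.bond_shifts,
        params.k,
        params.normalize_stretch,
        want_grad=False,
    )
    hinges = state.hinges()
    eb, _, per_hinge = _bend(state.positions, hinges, params.kappa, False)
    # attribute each hinge to the fiber of its center bond: hinges were
    # built per fiber in path order, so recover fiber ids the same way
    fiber_bend: dict[int, float] = {}
    fiber_len: dict[int, float] = {}
    fids = np.unique(state.fiber_id)
    for f in fids:
        fiber_len[int(f)] = float(
            state.rest_lengths[state.fiber_id == f].sum()
        )
        fiber_bend[int(f)] = 0.0
    idx = 0
    for path, f in zip(state.fiber_paths(), _path_fiber_ids(state)):
        nh = max(path.size - 2, 0)
        if nh:
            fiber_bend[int(f)] += float(per_hinge[idx : idx + nh].sum())
            idx += nh
    density = {
        f: fiber_bend[f] / fiber_len[f] for f in fiber_bend if fiber_len[f] > 0
    }
    n_fibers = max(len(fids), 1)
    return EnergyBreakdown(
        stretch=es,
        bend=eb,
        per_fiber_bend_density=density,
        mean_energy_per_fiber=(es + eb) / n_fibers,
    )


def _path_fiber_ids(state: NetworkState) -> list[int]:
    """Fiber id for each entry of ``state.fiber_paths()`` (same order).

    Paths are built by splitting bonds grouped on ascending fiber id, so
    the order is simply the sorted unique ids.
    """
    return [int(f) for f in np.unique(state.fiber_id)]


# -- DOF packing -----------------------------------------------------------

class _DofMap:
    """Pack free node coordinates (and circle angles) into a flat vector."""

    def __init__(self, state: NetworkState):
        circ_nodes = (
            np.concatenate([c.nodes for c in state.circle_constraints])
            if state.circle_constraints
            else np.zeros(0, dtype=np.int64)
        )
        self.circ_nodes = circ_nodes
        on_circle = np.zeros(state.n_nodes, dtype=bool)
        on_circle[circ_nodes] = True
        self.free_nodes = np.flatnonzero(state.free & ~on_circle)
        self.centers = (
            np.concatenate(
                [np.tile(c.center, (len(c.nodes), 1)) for c in state.circle_constraints]
            )
            if state.circle_constraints
            else np.zeros((0, 2))
        )
        self.radii = (
            np.concatenate(
                [np.full(len(c.nodes), c.radius) for c in state.circle_constraints]
            )
            if state.circle_constraints
            else np.zeros(0)
        )
        self.n_free = self.free_nodes.size
        self.n_circ = circ_nodes.size

    def pack(self, positions: np.ndarray) -> np.ndarray:
        x = np.empty(2 * self.n_free + self.n_circ)
        x[: 2 * self.n_free] = positions[self.free_nodes].ravel()
        if self.n_circ:
            rel = positions[self.circ_nodes] - self.centers
            x[2 * self.n_free :] = np.arctan2(rel[:, 1], rel[:, 0])
        return x

    def unpack(self, x: np.ndarray, positions: np.ndarray) -> np.ndarray:
        positions[self.free_nodes] = x[: 2 * self.n_free].reshape(-1, 2)
        if self.n_circ:
            phi = x[2 * self.n_free :]
            positions[self.circ_nodes, 0] = self.centers[:, 0] + self.radii * np.cos(phi)
            positions[self.circ_nodes, 1] = self.centers[:, 1] + self.radii * np.sin(phi)
        return positions

    def project_grad(self, x: np.ndarray, grad: np.ndarray) -> np.ndarray:
        g = np.empty_like(x)
        g[: 2 * self.n_free] = grad[self.free_nodes].ravel()
        if self.n_circ:
            phi = x[2 * self.n_free :]
            tx = -self.radii * np.sin(phi)
            ty = self.radii * np.cos(phi)
            gc = grad[self.circ_nodes]
            g[2 * self.n_free :] = gc[:, 0] * tx + gc[:, 1] * ty
        return g


def _energy_grad_core_entry(
    positions, bi, bj, rest, shifts, params, ha, hb, hc, su, sv, grad_buf
):
    from ._kernels import _energy_grad_core

    return _energy_grad_core(
        positions, bi, bj, rest, shifts, params.k,
        params.normalize_stretch, params.kappa,
        ha, hb, hc, su, sv, grad_buf,
    )


@dataclass
class MinimizeResult:
    state: NetworkState
    energy: EnergyBreakdown
    converged: bool
    grad_norm: float
    n_iter: int
    message: str = ""


def minimize(
    state: NetworkState,
    params: ElasticParams,
    grad_tol: float = 1.0e-8,
    max_iter: int = 20000,
    method: str = "auto",
    external_forces: np.ndarray | None = None,
    in_place: bool = False,
    warn: bool = True,
) -> MinimizeResult:
    """Relax the network to mechanical equilibrium.

    ``method='auto'`` uses limited-memory quasi-Newton (L-BFGS-B), which on
    these ill-conditioned bending-dominated landscapes is substantially
    more robust than nonlinear conjugate gradient; ``method='cg'`` runs
    Polak-Ribiere CG first with a quasi-Newton polish.  Non-convergence is
    flagged on the result (and warned), never silent.
    """
    from ._kernels import _energy_grad_core

    work = state if in_place else state.copy()
    dof = _DofMap(work)
    positions = work.positions
    hinges = work.hinges()

    if dof.n_free == 0 and dof.n_circ == 0:
        bd, grad = total_energy_and_gradient(work, params, external_forces)
        return MinimizeResult(work, bd, True, 0.0, 0, "no free DOFs")

    bi = np.ascontiguousarray(work.bonds[:, 0])
    bj = np.ascontiguousarray(work.bonds[:, 1])
    ha, hb, hc, su, sv = hinges
    grad_buf = np.zeros_like(positions)

    # FIRE handles the common unconstrained case entirely in compiled code;
    # the quasi-Newton path remains for circle constraints, external forces
    # and as a safety net (FIRE is inertial, so guard against the rare
    # trajectory that ends above its starting energy).
    from ._kernels import HAVE_NUMBA, fire_minimize

    if (
        method == "auto"
        and HAVE_NUMBA
        and external_forces is None
        and dof.n_circ == 0
    ):
        free_mask = np.ascontiguousarray(work.free)
        backup = positions.copy()
        grad_buf[:] = 0.0
        es0, eb0 = _energy_grad_core_entry(
            positions, bi, bj, work.rest_lengths, work.bond_shifts,
            params, ha, hb, hc, su, sv, grad_buf,
        )
        # FIRE budget: cheap compiled iterations first; landscapes it cannot
        # finish within the budget fall through to the quasi-Newton polish
        n_steps, fmax = fire_minimize(
            positions, free_mask, bi, bj, work.rest_lengths,
            work.bond_shifts, params.k, params.normalize_stretch,
            params.kappa, ha, hb, hc, su, sv, float(grad_tol),
            int(min(4000, 10 * max_iter)),
        )
        grad_buf[:] = 0.0
        es1, eb1 = _energy_grad_core_entry(
            positions, bi, bj, work.rest_lengths, work.bond_shifts,
            params, ha, hb, hc, su, sv, grad_buf,
        )
        if fmax <= grad_tol and es1 + eb1 <= es0 + eb0 + 1e-12:
            return MinimizeResult(
                work,
                EnergyBreakdown(stretch=es1, bend=eb1),
                True,
                float(fmax),
                int(n_steps),
                "FIRE converged",
            )
        if es1 + eb1 > es0 + eb0:
            positions[:] = backup  # discard the failed inertial trajectory
        # otherwise keep the partial FIRE progress and polish below

    def fun(x: np.ndarray):
        dof.unpack(x, positions)
        grad_buf[:] = 0.0
        es, eb = _energy_grad_core(
            positions, bi, bj, work.rest_lengths, work.bond_shifts,
            params.k, params.normalize_stretch, params.kappa,
            ha, hb, hc, su, sv, grad_buf,
        )
        e = es + eb
        grad = grad_buf
        if external_forces is not None:
            e -= float((external_forces * positions).sum())
            grad = grad - external_forces
        return e, dof.project_grad(x, grad)

    x0 = dof.pack(positions)
    nit = 0
    if method == "cg":
        res = scipy.optimize.minimize(
            fun,
            x0,
            jac=True,
            method="CG",
            options={"maxiter": max_iter, "gtol": grad_tol},
        )
        x0 = res.x
        nit += res.nit
    res = scipy.optimize.minimize(
        fun,
        x0,
        jac=True,
        method="L-BFGS-B",
        options={
            "maxiter": max_iter,
            "maxfun": 2 * max_iter,
            "gtol": grad_tol,
            "ftol": 1.0e-16,
            "maxcor": 12,
        },
    )
    nit += res.nit
    dof.unpack(res.x, positions)
    e, g = fun(res.x)
    gnorm = float(np.max(np.abs(g))) if g.size else 0.0
    converged = gnorm <= grad_tol * 10 or res.success
    bd, _ = total_energy_and_gradient(work, params)
    if not converged and warn:
        warnings.warn(
            f"minimization did not converge: |g|_max={gnorm:.3e} "
            f"(tol {grad_tol:.1e}), {res.message}",
            RuntimeWarning,
            stacklevel=2,
        )
    return MinimizeResult(work, bd, converged, gnorm, int(nit), str(res.message))


# -- shear protocol helpers ------------------------------------------------

def apply_shear(state: NetworkState, gamma: float, in_place: bool = True) -> NetworkState:
    """Apply an affine simple-shear increment ``x -> x + gamma * y``.

    ``y`` is measured from the bottom row.  All nodes (pinned ones
    included) are displaced, so pinned top/bottom rows end up held at
    their sheared positions; with periodic left/right boundaries the
    periodic images are unaffected (the repeat vector lies along x).
    The cumulative strain is tracked in ``state.meta['gamma']``.
    """
    work = state if in_place else state.copy()
    y0 = work.geometry.node_positions[:, 1].min()
    work.positions[:, 0] += gamma * (work.positions[:, 1] - y0)
    work.meta["gamma"] = work.meta.get("gamma", 0.0) + gamma
    return work


def shear_strain(state: NetworkState) -> float:
    """Mean x-displacement of the top boundary row over the network height."""
    geom = state.geometry
    nx, ny = geom.lattice_dims
    top = slice((ny - 1) * nx, ny * nx)
    dx = state.positions[top, 0] - geom.node_positions[top, 0]
    return float(dx.mean() / geom.height)


def differential_shear_modulus(
    state: NetworkState,
    params: ElasticParams,
    gamma: float,
    dgamma: float = 1.0e-3,
    grad_tol: float = 1.0e-8,
) -> float:
    """Differential modulus ``G(gamma) = d^2 (E/A) / d gamma^2``.

    Evaluated as a central second difference of the minimized energy
    density at ``gamma - dgamma, gamma, gamma + dgamma``; the input state
    is assumed relaxed at ``state.meta['gamma']`` (0 if absent) and each
    target strain is reached by incremental affine shearing with
    warm-started minimization.
    """
    area = state.geometry.width * state.geometry.height
    base = state.copy()
    g_cur = base.meta.get("gamma", 0.0)
    energies = []
    ok = True
    for g_target in (gamma - dgamma, gamma, gamma + dgamma):
        apply_shear(base, g_target - g_cur, in_place=True)
        g_cur = g_target
        res = minimize(base, params, grad_tol=grad_tol, in_place=True, warn=False)
        ok = ok and res.converged
        energies.append(res.energy.total)
    if not ok:
        warnings.warn(
            "differential_shear_modulus: a minimization did not fully "
            "converge; modulus may be inaccurate",
            RuntimeWarning,
            stacklevel=2,
        )
    em, e0, ep = energies
    return (ep - 2.0 * e0 + em) / (dgamma * dgamma * area)
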