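"""Irreversible cross-link dynamics: sliding and merging.

Two event families remodel the network topology while the elastic energy
is quasistatically minimized:

* **sliding** — when the net force one fiber exerts on another at a
  cross-link exceeds a threshold, the cross-link may rearrange: either one
  fiber's attachment *reconnects* to an adjacent node along the other
  fiber, or a fiber end terminating at the junction *peels* off (the
  junction splits).  Among the candidate local moves, the one with the
  lowest post-minimization energy is kept — and only if it strictly lowers
  the total elastic energy.  Sliding is deterministic by default.
* **merging** — node pairs on distinct fibers that approach within a
  critical distance fuse with probability ``p_merge`` per half-minute
  step: a permanent new bond is created at rest length equal to the
  current separation (stress-free at creation).  Merged bonds are never
  removed and never slide.

Both event types are intrinsically irreversible: sliding only ever lowers
the energy, and merged bonds persist after the load is removed, which is
what makes the deformation history-dependent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .lattice import NetworkState
from .mechanics import ElasticParams, minimize

__all__ = [
    "PlasticParams",
    "PlasticEvent",
    "crosslink_forces",
    "find_sliding_candidates",
    "apply_sliding_event",
    "find_merging_candidates",
    "apply_merging_event",
    "plastic_step",
]


@dataclass(frozen=True)
class PlasticParams:
    """Event rules for one half-minute plastic step.

    ``force_threshold`` is the cross-link force scale above which sliding
    is attempted (lattice units of ``k * a0``).  The default sits well
    inside the force distribution of a released network, so plastic
    activity persists after load release and the strain keeps decaying
    over minutes; the *rate* of rearrangement is limited by
    ``max_slide_events_per_step``, not by the threshold.  ``merge_radius``
    (default ``0.3 a0``) is well below the rest spacing, comparable to the
    spacing inside densified bundles.  ``slide_probability < 1`` switches
    sliding from deterministic to stochastic attempts.
    """

    force_threshold: float = 5.0e-4
    merge_radius: float = 0.3
    p_merge: float = 0.05
    dt_minutes: float = 0.5
    #: sliding passes per step.  One pass gives every loaded cross-link a
    #: single event attempt per half-minute tick, so stress released at one
    #: junction re-loads its surroundings only on the next tick — this is
    #: what spreads plastic activity over the multi-minute scale instead of
    #: exhausting it instantaneously.
    max_slide_passes: int = 1
    #: accepted sliding events per step.  Cross-links rearrange at a finite
    #: rate, so each half-minute tick fires at most this many events, the
    #: most-loaded junctions first; the backlog carries over to later
    #: ticks, which is what spreads the stress release over minutes and
    #: makes the post-release decay rate depend on the dwell history.
    max_slide_events_per_step: int | None = 5
    #: candidate junctions examined per step before giving up; candidates
    #: are ranked by force, so once the most-loaded junctions all reject,
    #: weaker ones essentially never accept.
    max_slide_attempts_per_step: int = 25
    slide_probability: float = 1.0
    #: radius (lattice units) of the frozen-far-field pre-screen used to
    #: rank candidate moves; ``None`` ranks by full minimization instead.
    screen_radius: float | None = 3.0
    screen_grad_tol: float = 1.0e-5
    accept_eps: float = 1.0e-12
    #: iteration cap for the global re-minimization following an accepted
    #: slide; the end-of-step minimization always runs to tolerance.
    slide_min_maxiter: int = 200
    #: a junction that rejected all its moves is not re-examined until its
    #: cross-link force changes by more than this amount (skips the
    #: re-screening churn on quiescent junctions; set to 0 to disable).
    reject_memo_tol: float = 1.0e-4
    #: when True, every accepted slide is followed by a global
    #: re-minimization and the acceptance test uses the globally minimized
    #: energy.  The default accepts on the frozen-far-field local energy
    #: balance (exact for the local term set) and re-minimizes globally
    #: once per step — far cheaper and still strictly energy-decreasing.
    global_min_every_slide: bool = False
    #: when True, a fiber end at an over-loaded junction may fully detach
    #: onto a fresh free node (the junction splits).  Off by default:
    #: sliding keeps fibers attached while their junction walks node by
    #: node (a terminating fiber's walk IS branch peeling — the branch
    #: point moves and the two fibers separate further), which lets
    #: material migrate under sustained load instead of being cut loose.
    peel_detachment: bool = False

    def __post_init__(self) -> None:
        if self.force_threshold < 0:
            raise ValueError("force_threshold must be >= 0")
        if not 0.0 <= self.p_merge <= 1.0:
            raise ValueError("p_merge must lie in [0, 1]")
        if self.merge_radius <= 0:
            raise ValueError("merge_radius must be > 0")
        if self.dt_minutes <= 0:
            raise ValueError("dt_minutes must be > 0")


@dataclass
class PlasticEvent:
    kind: str  # slide_reconnect | branch_peel | merge
    node: int
    nodes: tuple[int, ...]
    energy_before: float
    energy_after: float
    time_minutes: float = float("nan")
    detail: dict = field(default_factory=dict)

    @property
    def dE(self) -> float:
        return self.energy_after - self.energy_before


# -- cross-link forces -----------------------------------------------------

def crosslink_forces(
    state: NetworkState, params: ElasticParams
) -> dict[int, float]:
    """Force magnitude loaded on every cross-link.

    For each fiber incident at a cross-link node, the bond tensions of
    that fiber's bonds at the node are summed vectorially; the cross-link
    force is the largest magnitude over the incident fibers — the net
    force that fiber exerts on the rest of the junction.  Evaluated from
    bond tensions only (the bending contribution to junction load is
    neglected; tensions dominate at the strains where sliding activates).
    """
    xlinks = state.crosslinks()
    if xlinks.size == 0:
        return {}
    d = state.bond_vectors()
    length = np.linalg.norm(d, axis=1)
    coef = (
        params.k / state.rest_lengths
        if params.normalize_stretch
        else np.full(state.n_bonds, params.k)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        unit = np.where(length[:, None] > 0, d / length[:, None], 0.0)
    tension = coef * (length - state.rest_lengths)
    # tension vector acting on each endpoint, pointing along the bond away
    # from the endpoint when the bond is stretched
    tv_i = tension[:, None] * unit
    tv_j = -tv_i
    nodes = np.concatenate([state.bonds[:, 0], state.bonds[:, 1]])
    fibs = np.concatenate([state.fiber_id, state.fiber_id])
    tv = np.concatenate([tv_i, tv_j], axis=0)
    key = nodes.astype(np.int64) * (int(state.fiber_id.max()) + 1) + fibs
    uniq, inv = np.unique(key, return_inverse=True)
    fx = np.bincount(inv, tv[:, 0], uniq.size)
    fy = np.bincount(inv, tv[:, 1], uniq.size)
    mag = np.hypot(fx, fy)
    node_of = uniq // (int(state.fiber_id.max()) + 1)
    is_x = np.isin(node_of, xlinks)
    out: dict[int, float] = {int(n): 0.0 for n in xlinks}
    for n, m in zip(node_of[is_x], mag[is_x]):
        if m > out[int(n)]:
            out[int(n)] = float(m)
    return out


def find_sliding_candidates(
    state: NetworkState,
    elastic: ElasticParams,
    plastic: PlasticParams,
) -> list[tuple[int, float]]:
    """Cross-links loaded above threshold, sorted by descending force.

    Ties are broken by ascending node id so the deterministic event order
    is unambiguous.
    """
    forces = crosslink_forces(state, elastic)
    cands = [
        (n, f) for n, f in forces.items() if f > plastic.force_threshold
    ]
    cands.sort(key=lambda nf: (-nf[1], nf[0]))
    return cands


# -- sliding moves ---------------------------------------------------------

def _fibers_at_node(state: NetworkState, node: int) -> dict[int, list[int]]:
    """Non-merged fiber id -> bond rows incident at ``node``."""
    rows = np.flatnonzero(
        ((state.bonds[:, 0] == node) | (state.bonds[:, 1] == node))
        & ~state.merged
    )
    out: dict[int, list[int]] = {}
    for r in rows:
        out.setdefault(int(state.fiber_id[r]), []).append(int(r))
    return out


def _fiber_forces_at_node(
    state: NetworkState, node: int, elastic: ElasticParams
) -> dict[int, float]:
    """Net tension magnitude each incident fiber exerts at one node."""
    out: dict[int, float] = {}
    for fid, rows in _fibers_at_node(state, node).items():
        f = np.zeros(2)
        for r in rows:
            i, j = int(state.bonds[r, 0]), int(state.bonds[r, 1])
            d = state.positions[j] + state.bond_shifts[r] - state.positions[i]
            if j == node:
                d = -d
            length = float(np.linalg.norm(d))
            if length <= 0:
                continue
            coef = (
                elastic.k / state.rest_lengths[r]
                if elastic.normalize_stretch
                else elastic.k
            )
            f += coef * (length - state.rest_lengths[r]) * d / length
        out[fid] = float(np.linalg.norm(f))
    return out


def _enumerate_moves(
    state: NetworkState, node: int, movers=None, peel_detachment: bool = False
) -> list[dict]:
    """Local sliding moves at a junction, in deterministic order.

    Only the over-loaded fibers (``movers``; all incident fibers when
    ``None``) may move — it is the attachment carrying the excess force
    that detaches.  reconnect: the mover's bonds at the node reattach to a
    node adjacent along a host fiber.  peel: a mover end terminating at
    the junction splits off onto a fresh duplicate node.
    """
    fibers = _fibers_at_node(state, node)
    if len(fibers) < 2:
        return []
    moves: list[dict] = []
    fids = sorted(fibers)
    mover_fids = fids if movers is None else [f for f in fids if f in movers]
    for b_fid in mover_fids:
        b_rows = fibers[b_fid]
        others = [f for f in fids if f != b_fid]
        for a_fid in others:
            for a_row in fibers[a_fid]:
                i, j = state.bonds[a_row]
                m = int(j) if int(i) == node else int(i)
                s2 = state.bond_shifts[a_row].copy()
                if int(i) != node:  # orient host shift node -> m
                    s2 = -s2
                # self-loop check: no mover bond may already touch m
                ok = True
                for r in b_rows:
                    x = int(state.bonds[r, 0])
                    y = int(state.bonds[r, 1])
                    other = y if x == node else x
                    if other == m:
                        ok = False
                if ok:
                    moves.append(
                        {
                            "kind": "slide_reconnect",
                            "rows": tuple(b_rows),
                            "old": node,
                            "new": m,
                            "host_shift": s2,
                            "fiber": b_fid,
                        }
                    )
        if peel_detachment and len(b_rows) == 1:
            moves.append(
                {
                    "kind": "branch_peel",
                    "rows": tuple(b_rows),
                    "old": node,
                    "fiber": b_fid,
                }
            )
    return moves


def _apply_move(state: NetworkState, move: dict) -> None:
    """Mutate ``state`` topology in place; raises ValueError if the fiber
    would stop being a simple path."""
    if move["kind"] == "slide_reconnect":
        old, new = move["old"], move["new"]
        s2 = move["host_shift"]
        for r in move["rows"]:
            if int(state.bonds[r, 0]) == old:
                state.bonds[r, 0] = new
                state.bond_shifts[r] = state.bond_shifts[r] - s2
            else:
                state.bonds[r, 1] = new
                state.bond_shifts[r] = state.bond_shifts[r] + s2
    else:  # branch_peel
        old = move["old"]
        (r,) = move["rows"]
        new = state.n_nodes
        state.positions = np.vstack([state.positions, state.positions[old]])
        state.free = np.append(state.free, True)
        if int(state.bonds[r, 0]) == old:
            state.bonds[r, 0] = new
        else:
            state.bonds[r, 1] = new
        move["new"] = new
    state.invalidate_topology([move["fiber"]])
    state.fiber_topology()  # validates the path; raises if degenerate


def _local_relax(
    state: NetworkState,
    center: np.ndarray,
    radius: float,
    elastic: ElasticParams,
    grad_tol: float,
    relax: bool = True,
) -> float:
    """Relax only the nodes within ``radius`` of ``center`` (far field
    frozen) and return the energy of the *local* terms after relaxation.

    Works on a reduced subproblem — only bonds and hinges touching the
    local nodes enter the objective — so screening many candidate moves
    stays cheap.  The frozen far field contributes the same constant to
    every candidate move at a given junction, so the local energy ranks
    moves correctly even though it is not the total.
    """
    import scipy.optimize

    pos = state.positions
    local = state.free & (
        np.linalg.norm(pos - center, axis=1) <= radius
    )
    loc_nodes = np.flatnonzero(local)
    if loc_nodes.size == 0:
        return 0.0

    rows = np.flatnonzero(local[state.bonds[:, 0]] | local[state.bonds[:, 1]])
    sub_bonds = state.bonds[rows]
    sub_rest = state.rest_lengths[rows]
    sub_shift = state.bond_shifts[rows]

    topo = state.fiber_topology()
    touched_fids = sorted(set(int(f) for f in state.fiber_id[rows]))
    a_l, b_l, c_l, su_l, sv_l = [], [], [], [], []
    for fid in touched_fids:
        t = topo[fid]
        if t.path.size < 3:
            continue
        a, b, c = t.path[:-2], t.path[1:-1], t.path[2:]
        keep = local[a] | local[b] | local[c]
        if keep.any():
            a_l.append(a[keep])
            b_l.append(b[keep])
            c_l.append(c[keep])
            su_l.append(t.oshifts[:-1][keep])
            sv_l.append(t.oshifts[1:][keep])
    if a_l:
        sub_h = (
            np.concatenate(a_l),
            np.concatenate(b_l),
            np.concatenate(c_l),
            np.concatenate(su_l),
            np.concatenate(sv_l),
        )
    else:
        e = np.zeros(0, dtype=np.int64)
        sub_h = (e, e.copy(), e.copy(), np.zeros((0, 2)), np.zeros((0, 2)))

    from ._kernels import _energy_grad_core

    work = pos.copy()
    bi = np.ascontiguousarray(sub_bonds[:, 0])
    bj = np.ascontiguousarray(sub_bonds[:, 1])
    grad_buf = np.zeros_like(work)

    def sub_energy(p):
        grad_buf[:] = 0.0
        es, eb = _energy_grad_core(
            p, bi, bj, sub_rest, sub_shift,
            elastic.k, elastic.normalize_stretch, elastic.kappa,
            sub_h[0], sub_h[1], sub_h[2], sub_h[3], sub_h[4], grad_buf,
        )
        return es + eb, grad_buf

    def fun(x):
        work[loc_nodes] = x.reshape(-1, 2)
        e, g = sub_energy(work)
        return e, g[loc_nodes].ravel()

    if relax:
        res = scipy.optimize.minimize(
            fun,
            pos[loc_nodes].ravel(),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 150, "gtol": grad_tol, "ftol": 1e-14},
        )
        work[loc_nodes] = res.x.reshape(-1, 2)
        state.positions = work
    e_sub, _ = sub_energy(work)
    return float(e_sub)


def apply_sliding_event(
    state: NetworkState,
    node: int,
    elastic: ElasticParams,
    plastic: PlasticParams,
    energy_before: float | None = None,
    grad_tol: float = 1.0e-5,
) -> tuple[NetworkState, bool, PlasticEvent | None]:
    """Attempt the best sliding move at one over-loaded cross-link.

    Candidate moves are ranked by the energy after a local relaxation with
    the far field frozen (radius ``plastic.screen_radius``; ``None`` ranks
    by full minimization), then the best is re-minimized globally and kept
    iff it strictly lowers the total energy.  Returns the (possibly new)
    state, an acceptance flag and the event record.
    """
    if energy_before is None:
        res = minimize(state, elastic, grad_tol=grad_tol, warn=False)
        state, energy_before = res.state, res.energy.total
    forces = _fiber_forces_at_node(state, node, elastic)
    movers = {f for f, v in forces.items() if v > plastic.force_threshold}
    moves = _enumerate_moves(
        state, node, movers=movers, peel_detachment=plastic.peel_detachment
    )
    if not moves:
        return state, False, None

    center = state.positions[node].copy()
    screening = plastic.screen_radius is not None
    baseline_local = (
        _local_relax(
            state.copy(), center, plastic.screen_radius, elastic,
            plastic.screen_grad_tol, relax=False,
        )
        if screening
        else None
    )
    scored: list[tuple[float, int, NetworkState]] = []
    for k, move in enumerate(moves):
        trial = state.copy()
        try:
            _apply_move(trial, move)
        except ValueError:
            continue
        if screening:
            e = _local_relax(
                trial, center, plastic.screen_radius, elastic,
                plastic.screen_grad_tol,
            )
        else:
            res = minimize(
                trial, elastic, grad_tol=grad_tol, in_place=True, warn=False
            )
            e = res.energy.total
        scored.append((e, k, trial))
    if not scored:
        return state, False, None
    scored.sort(key=lambda t: (t[0], t[1]))
    e_screen, k_best, best = scored[0]
    if screening and e_screen >= baseline_local - plastic.accept_eps:
        # frozen-far-field relaxation predicts no gain; skip the full solve
        return state, False, None
    if screening and not plastic.global_min_every_slide:
        # frozen-far-field accounting: the far terms are identical before
        # and after the move, so the exact total at the locally relaxed
        # configuration is E_before - E_local_before + E_local_after; the
        # subsequent global minimization (once per step) only lowers it.
        e_after = energy_before - baseline_local + e_screen
    else:
        res = minimize(
            best,
            elastic,
            grad_tol=grad_tol,
            max_iter=plastic.slide_min_maxiter if screening else 20000,
            in_place=True,
            warn=False,
        )
        best = res.state
        e_after = res.energy.total
    if e_after < energy_before - plastic.accept_eps:
        move = moves[k_best]
        nodes = (move["old"], move.get("new", -1))
        ev = PlasticEvent(
            kind=move["kind"],
            node=int(node),
            nodes=tuple(int(v) for v in nodes),
            energy_before=float(energy_before),
            energy_after=float(e_after),
            detail={"rows": tuple(int(r) for r in move["rows"])},
        )
        return best, True, ev
    return state, False, None


# -- merging ---------------------------------------------------------------

def _node_fiber_sets(state: NetworkState) -> dict[int, set[int]]:
    out: dict[int, set[int]] = {}
    for (a, b), f in zip(state.bonds, state.fiber_id):
        out.setdefault(int(a), set()).add(int(f))
        out.setdefault(int(b), set()).add(int(f))
    return out


def find_merging_candidates(
    state: NetworkState, params: PlasticParams
) -> list[tuple[int, int, np.ndarray]]:
    """Node pairs on distinct fibers within ``merge_radius`` of each other.

    Returns sorted ``(i, j, image_shift)`` triples with ``i < j``;
    ``image_shift`` is the periodic image offset of ``j`` that realizes
    the close approach (nonzero only across a periodic seam).
    """
    r = params.merge_radius
    pos = state.positions
    fiber_sets = _node_fiber_sets(state)
    connected = {int(n) for n in fiber_sets}
    bonded = set()
    for a, b in state.bonds:
        bonded.add((min(int(a), int(b)), max(int(a), int(b))))

    tree = cKDTree(pos)
    raw: dict[tuple[int, int], np.ndarray] = {}
    for i, j in tree.query_pairs(r):
        raw[(min(i, j), max(i, j))] = np.zeros(2)
    if state.geometry.boundary_spec.x_periodic:
        lx = state.geometry.width
        xmin = pos[:, 0].min()
        strip = np.flatnonzero(pos[:, 0] <= xmin + r + 1.0)
        if strip.size:
            shifted = pos[strip] + np.array([lx, 0.0])
            for si, nbrs in zip(strip, tree.query_ball_point(shifted, r)):
                for u in nbrs:
                    if u == si:
                        continue
                    a, b = (int(u), int(si))  # j = si seen at +Lx image
                    key = (min(a, b), max(a, b))
                    if key not in raw:
                        shift = np.array([lx, 0.0])
                        if key[0] != a:  # stored i is the shifted node
                            shift = -shift
                        raw[key] = shift

    out = []
    for (i, j), shift in sorted(raw.items()):
        if i not in connected or j not in connected:
            continue
        if (i, j) in bonded:
            continue
        if fiber_sets[i] & fiber_sets[j]:
            continue
        # a freshly peeled twin can coincide with its origin; a zero-length
        # bond is degenerate, so require a finite separation
        sep = pos[j] + shift - pos[i]
        if float(np.linalg.norm(sep)) < 1.0e-3:
            continue
        out.append((i, j, shift))
    return out


def apply_merging_event(
    state: NetworkState,
    pair: tuple[int, int, np.ndarray],
    rng: np.random.Generator,
    params: PlasticParams,
) -> tuple[NetworkState, bool]:
    """With probability ``p_merge`` fuse a candidate pair in place.

    The new bond is created at rest length equal to the current node
    separation, so the merge is stress-free at the instant of creation;
    it is flagged permanent (``merged``) and forms its own single-bond
    fiber, carrying no bending hinge.
    """
    if rng.random() >= params.p_merge:
        return state, False
    i, j, shift = pair
    sep = state.positions[j] + shift - state.positions[i]
    dist = float(np.linalg.norm(sep))
    new_fid = int(state.fiber_id.max()) + 1 if state.n_bonds else 0
    state.bonds = np.vstack([state.bonds, [i, j]]).astype(np.int64)
    state.rest_lengths = np.append(state.rest_lengths, dist)
    state.bond_shifts = np.vstack([state.bond_shifts, shift])
    state.fiber_id = np.append(state.fiber_id, new_fid)
    state.merged = np.append(state.merged, True)
    state.invalidate_topology([new_fid])
    return state, True


# -- one plastic clock tick ------------------------------------------------

def plastic_step(
    state: NetworkState,
    elastic: ElasticParams,
    plastic: PlasticParams,
    rng: np.random.Generator,
    time_minutes: float = float("nan"),
    grad_tol: float = 1.0e-5,
    energy_in: float | None = None,
    step_min_maxiter: int = 250,
) -> tuple[NetworkState, list[PlasticEvent], float]:
    """One ``dt_minutes`` tick of plastic dynamics on a minimized state.

    Phase 1 — sliding: candidates above threshold are processed in
    descending force order; the state is re-minimized after every accepted
    move.  Candidate forces are recomputed between passes, and passes
    repeat until one yields no acceptance (or ``max_slide_passes``).
    Phase 2 — merging: every candidate pair is tried once with
    ``p_merge``.  Phase 3 — final minimization.

    Returns ``(state, events, total_energy)``.  Deterministic for a fixed
    rng state.
    """
    if energy_in is None:
        res = minimize(state, elastic, grad_tol=grad_tol, warn=False)
        state, energy = res.state, res.energy.total
    else:
        energy = energy_in
    events: list[PlasticEvent] = []

    cap = plastic.max_slide_events_per_step
    n_slides = 0
    memo = state.meta.setdefault("_slide_reject_memo", {})
    for _ in range(plastic.max_slide_passes):
        cands = find_sliding_candidates(state, elastic, plastic)
        if plastic.slide_probability < 1.0:
            cands = [
                c for c in cands if rng.random() < plastic.slide_probability
            ]
        accepted_any = False
        n_tried = 0
        for node, force in cands:
            if cap is not None and n_slides >= cap:
                break
            if n_tried >= plastic.max_slide_attempts_per_step:
                break
            prev = memo.get(node)
            if (
                prev is not None
                and abs(force - prev) <= plastic.reject_memo_tol
            ):
                continue  # nothing changed at this junction since it rejected
            n_tried += 1
            state, acc, ev = apply_sliding_event(
                state,
                node,
                elastic,
                plastic,
                energy_before=energy,
                grad_tol=grad_tol,
            )
            memo = state.meta.setdefault("_slide_reject_memo", {})
            if acc:
                energy = ev.energy_after
                ev.time_minutes = time_minutes
                events.append(ev)
                accepted_any = True
                n_slides += 1
                memo.pop(node, None)
            else:
                memo[node] = force
        if not accepted_any or (cap is not None and n_slides >= cap):
            break

    n_merged = 0
    for pair in find_merging_candidates(state, plastic):
        state, created = apply_merging_event(state, pair, rng, plastic)
        if created:
            n_merged += 1
            events.append(
                PlasticEvent(
                    kind="merge",
                    node=int(pair[0]),
                    nodes=(int(pair[0]), int(pair[1])),
                    energy_before=energy,
                    energy_after=energy,
                    time_minutes=time_minutes,
                )
            )
    # end-of-step equilibration: iteration-capped — the residual soft-mode
    # forces are orders of magnitude below the event threshold and keep
    # relaxing on subsequent ticks
    res = minimize(
        state, elastic, grad_tol=grad_tol, max_iter=step_min_maxiter,
        in_place=True, warn=False,
    )
    return res.state, events, res.energy.total


def events_to_frame(events: list[PlasticEvent]):
    """Event log as a tidy DataFrame (t_min, kind, nodes, dE)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "t_min": [e.time_minutes for e in events],
            "kind": [e.kind for e in events],
            "node": [e.node for e in events],
            "nodes": [";".join(str(n) for n in e.nodes) for e in events],
            "dE": [e.dE for e in events],
        }
    )
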