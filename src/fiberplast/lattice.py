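"""Diluted triangular-lattice fiber networks.

The network lives on a 2D triangular lattice with unit bond length
(lattice constant ``a0 = 1``).  Nodes are indexed by axial coordinates
``(i, j)`` with basis vectors ``(1, 0)`` and ``(1/2, sqrt(3)/2)``, so the
undeformed domain is a rhombus of ``nx`` columns and ``ny`` rows.  Each of
the ``3 nx ny`` candidate nearest-neighbour bonds is retained independently
with probability ``p`` (bond dilution); maximal chains of consecutive
collinear bonds are grouped into *fibers*, the units that carry bending
energy.  Nodes where two or more distinct fibers meet are *cross-links*.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np

A0 = 1.0
#: area of one undeformed lattice triangle (side a0 = 1)
TRIANGLE_AREA = np.sqrt(3.0) / 4.0

#: the three lattice directions, as (di, dj) axial steps
_DIRECTIONS = ((1, 0), (0, 1), (-1, 1))

_BOUNDARY_TAGS = frozenset({"free", "fixed", "periodic", "zero_stress"})


@dataclass(frozen=True)
class BoundarySpec:
    """Per-edge boundary condition tags.

    ``left``/``right`` may be ``free`` or ``periodic`` (jointly);
    ``top``/``bottom`` may be ``free``, ``fixed`` or ``zero_stress``.
    ``zero_stress`` is mechanically identical to ``free`` (tractions vanish
    on an unconstrained boundary) but marks an edge that was released.
    """

    left: str = "free"
    right: str = "free"
    top: str = "free"
    bottom: str = "free"

    def __post_init__(self) -> None:
        for tag in (self.left, self.right, self.top, self.bottom):
            if tag not in _BOUNDARY_TAGS:
                raise ValueError(f"unknown boundary tag {tag!r}")
        if (self.left == "periodic") != (self.right == "periodic"):
            raise ValueError("left/right periodicity must match")
        if "periodic" in (self.top, self.bottom):
            raise ValueError("top/bottom periodicity is not supported")

    @property
    def x_periodic(self) -> bool:
        return self.left == "periodic"


@dataclass
class NetworkGeometry:
    """Undeformed lattice geometry plus the full candidate bond set."""

    node_positions: np.ndarray  # (N, 2)
    lattice_dims: tuple[int, int]  # (nx, ny)
    boundary_spec: BoundarySpec
    candidate_bonds: np.ndarray  # (Mc, 2) node indices
    candidate_shifts: np.ndarray  # (Mc, 2) periodic image offsets
    candidate_dirs: np.ndarray  # (Mc,) direction index 0..2

    @property
    def n_nodes(self) -> int:
        return self.node_positions.shape[0]

    @property
    def width(self) -> float:
        """Periodic repeat length in x (``nx`` lattice units)."""
        return float(self.lattice_dims[0])

    @property
    def height(self) -> float:
        nx, ny = self.lattice_dims
        return (ny - 1) * np.sqrt(3.0) / 2.0

    def node_index(self, i: int, j: int) -> int:
        nx, ny = self.lattice_dims
        return j * nx + i


def build_triangular_lattice(
    nx: int, ny: int, boundary_spec: BoundarySpec | None = None
) -> NetworkGeometry:
    """Construct an ``nx x ny`` triangular lattice with unit spacing.

    Returns the geometry with all nearest-neighbour bonds listed as
    candidates (they become actual bonds on dilution).  With periodic
    left/right boundaries, bonds wrap in the ``i`` direction and carry an
    image shift of ``+-nx`` in x.
    """
    if nx < 2 or ny < 2:
        raise ValueError(f"lattice dimensions must be >= 2, got {nx}x{ny}")
    boundary = boundary_spec or BoundarySpec()

    jj, ii = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
    xs = ii.ravel() + jj.ravel() / 2.0
    ys = jj.ravel() * (np.sqrt(3.0) / 2.0)
    positions = np.column_stack([xs, ys]).astype(float)

    periodic = boundary.x_periodic
    bonds, shifts, dirs = [], [], []
    for d, (di, dj) in enumerate(_DIRECTIONS):
        for j in range(ny):
            j2 = j + dj
            if j2 >= ny:
                continue
            for i in range(nx):
                i2 = i + di
                shift_x = 0.0
                if i2 >= nx or i2 < 0:
                    if not periodic:
                        continue
                    shift_x = float(nx) if i2 >= nx else -float(nx)
                    i2 %= nx
                bonds.append((j * nx + i, j2 * nx + i2))
                shifts.append((shift_x, 0.0))
                dirs.append(d)

    return NetworkGeometry(
        node_positions=positions,
        lattice_dims=(nx, ny),
        boundary_spec=boundary,
        candidate_bonds=np.asarray(bonds, dtype=np.int64),
        candidate_shifts=np.asarray(shifts, dtype=float),
        candidate_dirs=np.asarray(dirs, dtype=np.int64),
    )


@dataclass
class CircleConstraint:
    """Nodes confined to a rigid circle, free to slide tangentially."""

    nodes: np.ndarray  # (n,) node indices
    center: np.ndarray  # (2,)
    radius: float


@dataclass
class FiberTopo:
    """Ordered realization of one fiber: a simple path of bonds.

    ``rows`` are bond-array rows in path order; ``path`` the node sequence
    (``len(rows) + 1`` entries); ``oshifts[t]`` the periodic image shift of
    the step ``path[t] -> path[t+1]``.
    """

    rows: np.ndarray
    path: np.ndarray
    oshifts: np.ndarray


@dataclass
class NetworkState:
    """Mutable mechanical configuration of a diluted network.

    Bond ``m`` connects ``bonds[m, 0] -> bonds[m, 1]``; its geometric
    vector is ``positions[j] + bond_shifts[m] - positions[i]`` so that
    bonds wrapping a periodic edge remain unit length.  ``fiber_id[m]``
    assigns every bond to exactly one fiber; fibers are simple paths.
    """

    geometry: NetworkGeometry
    positions: np.ndarray  # (N, 2) current coordinates
    bonds: np.ndarray  # (M, 2)
    rest_lengths: np.ndarray  # (M,)
    bond_shifts: np.ndarray  # (M, 2)
    fiber_id: np.ndarray  # (M,)
    merged: np.ndarray  # (M,) bool; merged bonds are permanent, hinge-free
    free: np.ndarray  # (N,) bool; False = both coordinates pinned
    circle_constraints: list[CircleConstraint] = field(default_factory=list)
    p: float = 1.0
    rng_seed: int | None = None
    meta: dict = field(default_factory=dict)
    _fibers: dict | None = field(default=None, repr=False)
    _hinge_cache: tuple | None = field(default=None, repr=False)

    # -- bookkeeping -------------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return self.positions.shape[0]

    @property
    def n_bonds(self) -> int:
        return self.bonds.shape[0]

    def invalidate_topology(self, fiber_ids=None) -> None:
        """Drop cached fiber paths/hinges after a topology change.

        Passing the ids of the fibers actually touched rebuilds only those
        lazily; bond rows are append-only, so cached entries for untouched
        fibers stay valid.
        """
        if fiber_ids is None or self._fibers is None:
            self._fibers = None
        else:
            for f in fiber_ids:
                self._fibers.pop(int(f), None)
        self._hinge_cache = None

    def copy(self) -> "NetworkState":
        new = NetworkState(
            geometry=self.geometry,
            positions=self.positions.copy(),
            bonds=self.bonds.copy(),
            rest_lengths=self.rest_lengths.copy(),
            bond_shifts=self.bond_shifts.copy(),
            fiber_id=self.fiber_id.copy(),
            merged=self.merged.copy(),
            free=self.free.copy(),
            circle_constraints=[
                CircleConstraint(c.nodes.copy(), c.center.copy(), c.radius)
                for c in self.circle_constraints
            ],
            p=self.p,
            rng_seed=self.rng_seed,
            # dict-valued meta entries (e.g. caches) must not be shared
            meta={
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in self.meta.items()
            },
        )
        # share topology caches: entries are replaced, never mutated
        new._fibers = dict(self._fibers) if self._fibers is not None else None
        new._hinge_cache = self._hinge_cache
        return new

    def bond_vectors(self) -> np.ndarray:
        """(M, 2) geometric bond vectors, periodic images applied."""
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        return self.positions[j] + self.bond_shifts - self.positions[i]

    def bond_lengths(self) -> np.ndarray:
        return np.linalg.norm(self.bond_vectors(), axis=1)

    def bond_midpoints(self) -> np.ndarray:
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        return 0.5 * (self.positions[i] + self.positions[j] + self.bond_shifts)

    def coordination(self) -> np.ndarray:
        """(N,) number of bonds incident at each node."""
        counts = np.bincount(self.bonds.ravel(), minlength=self.n_nodes)
        return counts

    # -- fiber structure ---------------------------------------------------
    def fiber_topology(self) -> dict[int, FiberTopo]:
        """Map fiber id -> ordered :class:`FiberTopo` (lazily cached)."""
        if self._fibers is None:
            self._fibers = {}
            order = np.argsort(self.fiber_id, kind="stable")
            fids = self.fiber_id[order]
            boundaries = np.flatnonzero(np.diff(fids)) + 1
            for grp in np.split(order, boundaries):
                if grp.size:
                    fid = int(self.fiber_id[grp[0]])
                    self._fibers[fid] = _build_fiber(self, grp)
        else:
            for fid in np.unique(self.fiber_id):
                if int(fid) not in self._fibers:
                    rows = np.flatnonzero(self.fiber_id == fid)
                    self._fibers[int(fid)] = _build_fiber(self, rows)
        return self._fibers

    def fiber_paths(self) -> list[np.ndarray]:
        """Ordered node paths, one per fiber, in ascending fiber-id order."""
        topo = self.fiber_topology()
        return [topo[f].path for f in sorted(topo)]

    def hinges(self) -> tuple:
        """Bending hinge arrays ``(a, b, c, shift_u, shift_v)`` (cached).

        A hinge is a pair of consecutive bonds within one fiber; the
        bending angle is measured between ``u = x_b + s_u - x_a`` and
        ``v = x_c + s_v - x_b``.  Hinges are concatenated in ascending
        fiber-id order.
        """
        if self._hinge_cache is None:
            topo = self.fiber_topology()
            a_l, b_l, c_l, su_l, sv_l = [], [], [], [], []
            for f in sorted(topo):
                t = topo[f]
                if t.path.size < 3:
                    continue
                a_l.append(t.path[:-2])
                b_l.append(t.path[1:-1])
                c_l.append(t.path[2:])
                su_l.append(t.oshifts[:-1])
                sv_l.append(t.oshifts[1:])
            if a_l:
                self._hinge_cache = (
                    np.concatenate(a_l),
                    np.concatenate(b_l),
                    np.concatenate(c_l),
                    np.concatenate(su_l),
                    np.concatenate(sv_l),
                )
            else:
                empty = np.zeros(0, dtype=np.int64)
                self._hinge_cache = (
                    empty,
                    empty.copy(),
                    empty.copy(),
                    np.zeros((0, 2)),
                    np.zeros((0, 2)),
                )
        return self._hinge_cache

    def crosslinks(self) -> np.ndarray:
        """Node indices where >= 2 distinct fibers meet."""
        if self.n_bonds == 0:
            return np.zeros(0, dtype=np.int64)
        nodes = self.bonds.ravel()
        fibs = np.repeat(self.fiber_id, 2)
        key = nodes.astype(np.int64) * (self.fiber_id.max() + 1) + fibs
        uniq = np.unique(key)
        node_of = uniq // (self.fiber_id.max() + 1)
        counts = np.bincount(node_of, minlength=self.n_nodes)
        return np.flatnonzero(counts >= 2)


def _build_fiber(state: NetworkState, rows: np.ndarray) -> FiberTopo:
    """Order a fiber's bond rows into a simple path (raises if not a path)."""
    rows = np.asarray(rows, dtype=np.int64)
    sub = state.bonds[rows]
    if rows.size == 1:
        return FiberTopo(
            rows=rows,
            path=sub[0].copy(),
            oshifts=state.bond_shifts[rows].copy(),
        )
    adj: dict[int, list[tuple[int, int]]] = {}
    for r, (a, b) in zip(rows, sub):
        adj.setdefault(int(a), []).append((int(b), int(r)))
        adj.setdefault(int(b), []).append((int(a), int(r)))
    ends = [n for n, nb in adj.items() if len(nb) == 1]
    if len(ends) != 2 or any(len(nb) > 2 for nb in adj.values()):
        raise ValueError(
            f"fiber {int(state.fiber_id[rows[0]])} is not a simple path"
        )
    start = min(ends)
    path = [start]
    row_order = []
    prev_row = -1
    cur = start
    for _ in range(rows.size):
        nxt = [(n, r) for n, r in adj[cur] if r != prev_row]
        node, row = nxt[0]
        path.append(node)
        row_order.append(row)
        prev_row = row
        cur = node
    row_order = np.asarray(row_order, dtype=np.int64)
    # oriented shifts: + if the bond is stored in traversal direction
    oshifts = state.bond_shifts[row_order].copy()
    stored_first = state.bonds[row_order, 0]
    flip = stored_first != np.asarray(path[:-1])
    oshifts[flip] *= -1.0
    return FiberTopo(
        rows=row_order, path=np.asarray(path, dtype=np.int64), oshifts=oshifts
    )


def dilute(geometry: NetworkGeometry, p: float, seed: int) -> NetworkState:
    """Retain each candidate bond independently with probability ``p``.

    Deterministic for fixed ``seed``; fibers are identified on the retained
    bond set and the free/pinned node mask is derived from the boundary
    tags (``fixed`` top/bottom rows are pinned).
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"bond probability must lie in [0, 1], got {p}")
    rng = np.random.default_rng(seed)
    keep = rng.random(geometry.candidate_bonds.shape[0]) < p

    bonds = geometry.candidate_bonds[keep]
    shifts = geometry.candidate_shifts[keep]
    dirs = geometry.candidate_dirs[keep]
    fiber_id = _initial_fibers(geometry, bonds, dirs)

    state = NetworkState(
        geometry=geometry,
        positions=geometry.node_positions.copy(),
        bonds=bonds.copy(),
        rest_lengths=np.full(bonds.shape[0], A0),
        bond_shifts=shifts.copy(),
        fiber_id=fiber_id,
        merged=np.zeros(bonds.shape[0], dtype=bool),
        free=_node_freedom(geometry),
        p=p,
        rng_seed=seed,
    )
    return state


def _node_freedom(geometry: NetworkGeometry) -> np.ndarray:
    nx, ny = geometry.lattice_dims
    free = np.ones(geometry.n_nodes, dtype=bool)
    b = geometry.boundary_spec
    if b.bottom == "fixed":
        free[0:nx] = False
    if b.top == "fixed":
        free[(ny - 1) * nx :] = False
    return free


def _initial_fibers(
    geometry: NetworkGeometry, bonds: np.ndarray, dirs: np.ndarray
) -> np.ndarray:
    """Partition lattice bonds into maximal collinear chains.

    Two retained bonds are in the same fiber iff they share a node and the
    same lattice direction.  On a periodic lattice a fully occupied row
    would form a cycle; one junction is cut (at the wrap bond) so fibers
    remain simple paths.
    """
    m = bonds.shape[0]
    fiber = np.full(m, -1, dtype=np.int64)
    # adjacency within each direction class: node -> bond rows
    by_node: dict[tuple[int, int], list[int]] = {}
    for row in range(m):
        d = int(dirs[row])
        for node in bonds[row]:
            by_node.setdefault((d, int(node)), []).append(row)

    next_id = 0
    cut_rows: list[int] = []
    for row in range(m):
        if fiber[row] >= 0:
            continue
        # flood the collinear chain containing this bond
        stack = [row]
        comp = []
        fiber[row] = next_id
        while stack:
            r = stack.pop()
            comp.append(r)
            d = int(dirs[r])
            for node in bonds[r]:
                for r2 in by_node[(d, int(node))]:
                    if fiber[r2] < 0:
                        fiber[r2] = next_id
                        stack.append(r2)
        if _is_closed_ring(bonds, comp):
            cut_rows.append(min(comp))
        next_id += 1
    # a collinear chain wrapping a periodic edge closes into a ring; split
    # one bond off into its own fiber so every fiber is a simple path
    for r in cut_rows:
        fiber[r] = next_id
        next_id += 1
    _, fiber = np.unique(fiber, return_inverse=True)
    return fiber.astype(np.int64)


def _is_closed_ring(bonds, comp) -> bool:
    if len(comp) < 2:
        return False
    deg: dict[int, int] = {}
    for r in comp:
        for node in bonds[r]:
            deg[int(node)] = deg.get(int(node), 0) + 1
    return all(v == 2 for v in deg.values())


def identify_fibers(state: NetworkState) -> NetworkState:
    """Re-derive the fiber partition from bond geometry (collinear chains).

    Groups bonds that share a node and are collinear (same undeformed
    lattice direction, by unit-vector comparison) into maximal chains.
    Intended for freshly built or hand-assembled states whose bonds still
    lie along lattice directions; plastic moves instead preserve fiber
    identity and only rebuild paths/hinges.
    """
    if state.n_bonds == 0:
        state.fiber_id = np.zeros(0, dtype=np.int64)
        state.invalidate_topology()
        return state
    vec = state.bond_vectors()
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    # canonical sign: first nonzero component positive
    flip = (unit[:, 0] < -1e-9) | (
        (np.abs(unit[:, 0]) < 1e-9) & (unit[:, 1] < 0)
    )
    unit[flip] *= -1.0
    dirs = np.zeros(state.n_bonds, dtype=np.int64)
    keys = {}
    for row, u in enumerate(np.round(unit, 6)):
        k = (u[0], u[1])
        dirs[row] = keys.setdefault(k, len(keys))
    state.fiber_id = _initial_fibers(state.geometry, state.bonds, dirs)
    state.invalidate_topology()
    return state


@dataclass(frozen=True)
class NetworkSummary:
    bond_count: int
    mean_coordination: float
    fiber_density_F: float  # bonds per unit area
    occupied_fraction: float


def expected_fiber_density(p: float) -> float:
    """Expected bond density 3p / (2 * triangle area) for occupation p."""
    return 3.0 * p / (2.0 * TRIANGLE_AREA)


def network_summary(state: NetworkState) -> NetworkSummary:
    """Bond count, coordination and areal fiber density of the full domain.

    The domain area is the undeformed lattice area: ``nx * (ny - 1)``
    triangle pairs for a periodic strip, ``(nx - 1/2) * (ny - 1)`` columns
    otherwise (the rhombus spans ``nx - 1`` full columns plus boundary
    half-triangles either way; we use the periodic repeat area so that a
    fully occupied lattice approaches the closed-form density).
    """
    geom = state.geometry
    nx, ny = geom.lattice_dims
    area = nx * (ny - 1) * 2 * TRIANGLE_AREA
    if area <= 0:
        raise ValueError("zero-area domain")
    n_candidates = geom.candidate_bonds.shape[0]
    occ = state.n_bonds / n_candidates if n_candidates else 0.0
    coord = state.coordination()
    mean_coord = float(coord.mean()) if state.n_nodes else 0.0
    return NetworkSummary(
        bond_count=int(state.n_bonds),
        mean_coordination=mean_coord,
        fiber_density_F=state.n_bonds / area,
        occupied_fraction=float(occ),
    )


# -- snapshot I/O ----------------------------------------------------------

def snapshot_dict(state: NetworkState) -> dict:
    """Self-describing snapshot of a network state (JSON-serializable)."""
    geom = state.geometry
    return {
        "nodes": [
            [int(n), float(x), float(y)]
            for n, (x, y) in enumerate(state.positions)
        ],
        "bonds": [
            [int(a), int(b), float(l0), int(f), int(mg), float(sx), float(sy)]
            for (a, b), l0, f, mg, (sx, sy) in zip(
                state.bonds,
                state.rest_lengths,
                state.fiber_id,
                state.merged,
                state.bond_shifts,
            )
        ],
        "free": [int(v) for v in state.free],
        "circles": [
            {
                "nodes": [int(n) for n in c.nodes],
                "center": [float(c.center[0]), float(c.center[1])],
                "radius": float(c.radius),
            }
            for c in state.circle_constraints
        ],
        "meta": {
            "p": state.p,
            "seed": state.rng_seed,
            "dims": list(geom.lattice_dims),
            "boundary": dataclasses.asdict(geom.boundary_spec),
            **{
                k: v
                for k, v in state.meta.items()
                if not k.startswith("_") and _jsonable(v)
            },
        },
    }


def _jsonable(v) -> bool:
    try:
        json.dumps(v)
        return True
    except TypeError:
        return False


def save_snapshot(state: NetworkState, path) -> None:
    with open(path, "w") as fh:
        json.dump(snapshot_dict(state), fh)


def load_snapshot(path) -> NetworkState:
    with open(path) as fh:
        data = json.load(fh)
    meta = data["meta"]
    boundary = BoundarySpec(**meta["boundary"])
    geom = build_triangular_lattice(*meta["dims"], boundary)
    nodes = np.asarray(data["nodes"], dtype=float)
    positions = nodes[:, 1:3].copy()
    bond_rows = np.asarray(data["bonds"], dtype=float)
    if bond_rows.size == 0:
        bond_rows = bond_rows.reshape(0, 7)
    state = NetworkState(
        geometry=geom,
        positions=positions,
        bonds=bond_rows[:, 0:2].astype(np.int64),
        rest_lengths=bond_rows[:, 2].copy(),
        bond_shifts=bond_rows[:, 5:7].copy(),
        fiber_id=bond_rows[:, 3].astype(np.int64),
        merged=bond_rows[:, 4].astype(bool),
        free=np.asarray(data["free"], dtype=bool),
        circle_constraints=[
            CircleConstraint(
                nodes=np.asarray(c["nodes"], dtype=np.int64),
                center=np.asarray(c["center"], dtype=float),
                radius=float(c["radius"]),
            )
            for c in data.get("circles", [])
        ],
        p=float(meta.get("p", 1.0)),
        rng_seed=meta.get("seed"),
        meta={
            k: v
            for k, v in meta.items()
            if k not in {"p", "seed", "dims", "boundary"}
        },
    )
    return state


def write_tables(state: NetworkState, nodes_path, bonds_path) -> None:
    """Write the state as two delimited-text tables (nodes.csv, bonds.csv)."""
    import pandas as pd

    pd.DataFrame(
        {
            "id": np.arange(state.n_nodes),
            "x": state.positions[:, 0],
            "y": state.positions[:, 1],
            "free": state.free.astype(int),
        }
    ).to_csv(nodes_path, index=False)
    pd.DataFrame(
        {
            "i": state.bonds[:, 0],
            "j": state.bonds[:, 1],
            "rest_length": state.rest_lengths,
            "fiber_id": state.fiber_id,
            "merged": state.merged.astype(int),
            "shift_x": state.bond_shifts[:, 0],
            "shift_y": state.bond_shifts[:, 1],
        }
    ).to_csv(bonds_path, index=False)
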