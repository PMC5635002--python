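"""Quantification and fitting: bundle density, alignment, relaxation, compliance.

The structural readout of bundle formation is the relative fiber-density
increase ``dF/F = (F_b - F) / F`` between the region of bundle (ROB, the
rectangle spanning the gap between two contracting cells) and the
background network.  Alignment is quantified by the 2D nematic order
parameter.  Strain-relaxation curves are fitted with single- or
double-exponential kinetics (the latter optionally with a shared fast
timescale across dwell times), and local mechanical anisotropy is probed
by the directional compliance J(theta) and its compliance-ellipse aspect
ratio.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.optimize

from .lattice import NetworkState
from .mechanics import ElasticParams, minimize

__all__ = [
    "BundleMetrics",
    "RelaxationSeries",
    "ExponentialFit",
    "DoubleExponentialFit",
    "ComplianceProbe",
    "bundle_density_ratio",
    "nematic_order",
    "fit_single_exponential",
    "fit_double_exponential",
    "probe_compliance",
]


# -- bundle density --------------------------------------------------------

@dataclass(frozen=True)
class BundleMetrics:
    F_background: float  # bonds per unit area far from the bundle
    F_bundle: float  # bonds per unit area in the region of bundle
    delta_F_over_F: float
    nematic_S: float  # alignment of the ROB bonds
    n_bundle_bonds: int
    rob_area: float


def _segment_fraction_inside_circle(p0, p1, center, radius):
    """Fraction of each segment's length lying inside a circle (vectorized)."""
    d = p1 - p0
    f = p0 - center
    a = np.einsum("ij,ij->i", d, d)
    b = 2.0 * np.einsum("ij,ij->i", f, d)
    c = np.einsum("ij,ij->i", f, f) - radius**2
    frac = np.zeros(p0.shape[0])
    disc = b * b - 4 * a * c
    ok = (disc > 0) & (a > 0)
    sq = np.sqrt(np.where(ok, disc, 0.0))
    t1 = np.clip((-b - sq) / (2 * a + ~ok), 0.0, 1.0)
    t2 = np.clip((-b + sq) / (2 * a + ~ok), 0.0, 1.0)
    frac[ok] = (t2 - t1)[ok]
    return frac


def bundle_density_ratio(
    state: NetworkState,
    cells,
    rob_width: float | None = None,
    membership: str = "midpoint",
    domain: str = "fixed",
) -> BundleMetrics:
    """Relative fiber-density increase between two cells.

    The region of bundle (ROB) is the rectangle spanning the gap between
    the two cell surfaces along the center-to-center line, of width equal
    to the cell diameter (override with ``rob_width``).  The background
    density is measured over the rest of the domain excluding the two
    cell disks and the ROB.  A bond is counted inside a region if its
    midpoint falls inside (``membership='midpoint'``) or in proportion to
    the overlapping length (``membership='overlap'``).

    ``domain='fixed'`` (default) normalizes the background by the
    *undeformed* lattice area — the analog of densities measured in a
    fixed microscope frame, so material migrating toward the cells lowers
    the background instead of the frame shrinking with the network;
    ``domain='hull'`` uses the convex hull of the current configuration.
    """
    from scipy.spatial import ConvexHull

    if len(cells) != 2:
        raise ValueError("bundle_density_ratio expects exactly two cells")
    c0 = np.asarray(cells[0].center, dtype=float)
    c1 = np.asarray(cells[1].center, dtype=float)
    r0, r1 = float(cells[0].radius), float(cells[1].radius)
    axis = c1 - c0
    dist = float(np.linalg.norm(axis))
    gap = dist - r0 - r1
    if gap <= 0:
        raise ValueError("cells touch or overlap: zero-area ROB")
    u = axis / dist
    v = np.array([-u[1], u[0]])
    width = rob_width if rob_width is not None else r0 + r1
    origin = c0 + u * r0  # surface of cell 0 on the center line

    mids = state.bond_midpoints()
    rel = mids - origin
    s = rel @ u
    t = rel @ v
    in_rob = (s >= 0) & (s <= gap) & (np.abs(t) <= width / 2.0)

    if membership == "overlap":
        # length-weighted membership via fine sub-sampling of each bond
        i, j = state.bonds[:, 0], state.bonds[:, 1]
        p0 = state.positions[i]
        p1 = state.positions[j] + state.bond_shifts
        ts = np.linspace(0.0, 1.0, 9)
        frac = np.zeros(state.n_bonds)
        for tt in ts:
            pt = p0 + tt * (p1 - p0) - origin
            ss, tv = pt @ u, pt @ v
            frac += (ss >= 0) & (ss <= gap) & (np.abs(tv) <= width / 2.0)
        w_rob = frac / len(ts)
    elif membership == "midpoint":
        w_rob = in_rob.astype(float)
    else:
        raise ValueError(f"unknown membership rule {membership!r}")

    in_cell0 = np.linalg.norm(mids - c0, axis=1) <= r0
    in_cell1 = np.linalg.norm(mids - c1, axis=1) <= r1
    in_cells = in_cell0 | in_cell1

    rob_area = gap * width
    if domain == "hull":
        hull = ConvexHull(state.positions)
        domain_area = float(hull.volume)  # 2D: volume is the area
    elif domain == "fixed":
        nx, ny = state.geometry.lattice_dims
        from .lattice import TRIANGLE_AREA

        domain_area = nx * (ny - 1) * 2 * TRIANGLE_AREA
    else:
        raise ValueError(f"unknown domain rule {domain!r}")
    bg_area = domain_area - rob_area - np.pi * (r0**2 + r1**2)
    if bg_area <= 0:
        raise ValueError("background region has non-positive area")

    n_rob = float(w_rob.sum())
    n_bg = float(((1.0 - w_rob) * ~in_cells).sum())
    f_bundle = n_rob / rob_area
    f_bg = n_bg / bg_area
    s_rob = nematic_order(state, in_rob) if in_rob.any() else float("nan")
    return BundleMetrics(
        F_background=f_bg,
        F_bundle=f_bundle,
        delta_F_over_F=(f_bundle - f_bg) / f_bg,
        nematic_S=s_rob,
        n_bundle_bonds=int(in_rob.sum()),
        rob_area=rob_area,
    )


def nematic_order(state: NetworkState, region=None) -> float:
    """2D nematic order parameter of bond orientations, length-weighted.

    ``S = <cos 2(theta - theta_bar)>`` with ``theta_bar`` the principal
    direction; equivalently the modulus of the length-weighted average of
    ``exp(2 i theta)``.  1 for parallel bonds, 0 for an isotropic (or
    three-fold symmetric) distribution.  ``region`` is an optional boolean
    bond mask.
    """
    vec = state.bond_vectors()
    if region is not None:
        vec = vec[np.asarray(region, dtype=bool)]
    if vec.shape[0] == 0:
        raise ValueError("nematic_order: empty region")
    length = np.linalg.norm(vec, axis=1)
    theta = np.arctan2(vec[:, 1], vec[:, 0])
    wc = float((length * np.cos(2 * theta)).sum())
    ws = float((length * np.sin(2 * theta)).sum())
    return float(np.hypot(wc, ws) / length.sum())


# -- relaxation kinetics ---------------------------------------------------

@dataclass
class RelaxationSeries:
    """A strain-relaxation record ``eps(t)`` after load release.

    ``t`` in minutes with ``t = 0`` the instant of release; ``eps0`` the
    held strain and ``eps0_plus`` the strain right after the instantaneous
    elastic drop.
    """

    t: np.ndarray
    strain: np.ndarray
    eps0: float = float("nan")
    eps0_plus: float = float("nan")
    dwell_minutes: float = float("nan")
    meta: dict = field(default_factory=dict)


@dataclass
class ExponentialFit:
    amplitude: float
    tau: float  # same unit as the time axis
    offset: float
    residual_norm: float
    converged: bool

    def __call__(self, t):
        return self.amplitude * np.exp(-np.asarray(t) / self.tau) + self.offset


def fit_single_exponential(
    t: np.ndarray, y: np.ndarray, t_range: tuple[float, float] | None = None
) -> ExponentialFit:
    """Least-squares fit of ``A exp(-t / tau) + c``.

    Initializes ``c`` from the tail, ``A`` from the head and ``tau`` from a
    log-linear regression; refines with bounded least squares.  A
    non-convergent fit is returned flagged, never raised.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if t_range is not None:
        m = (t >= t_range[0]) & (t <= t_range[1])
        t, y = t[m], y[m]
    if t.size < 4:
        raise ValueError("need at least 4 points for an exponential fit")
    order = np.argsort(t)
    t, y = t[order], y[order]
    span = float(np.ptp(t))
    c0 = float(y[-max(2, t.size // 5):].mean())
    a0 = float(y[0] - c0)
    if abs(a0) < 1e-14 * max(1.0, abs(c0)):
        resid = y - c0
        return ExponentialFit(0.0, span, c0, float(np.linalg.norm(resid)), True)
    # log-linear regression on the decaying part for the rate initial guess
    rel = (y - c0) / a0
    pos = (rel > 1e-10) & (rel < 1e6) & np.isfinite(rel)
    tau0 = span / 3
    if abs(a0) > 1e-6 and pos.sum() >= 3:
        try:
            slope = np.polyfit(t[pos], np.log(rel[pos]), 1)[0]
            if np.isfinite(slope):
                tau0 = 1.0 / max(1.0 / (span * 30), -slope)
        except np.linalg.LinAlgError:
            pass
    tau0 = float(np.clip(tau0, span * 1e-2, span * 30))

    def model(params):
        a, log_tau, c = params
        return a * np.exp(-t / np.exp(log_tau)) + c - y

    best = None
    for tv in {tau0, span / 10, span}:
        res = scipy.optimize.least_squares(
            model, x0=[a0, np.log(tv), c0], method="lm", max_nfev=5000
        )
        if best is None or res.cost < best.cost:
            best = res
    a, log_tau, c = best.x
    return ExponentialFit(
        amplitude=float(a),
        tau=float(np.exp(log_tau)),
        offset=float(c),
        residual_norm=float(np.linalg.norm(best.fun)),
        converged=bool(best.success),
    )


@dataclass
class DoubleExponentialFit:
    """Joint double-exponential fit across relaxation series.

    Model per series: ``eps(t) = a exp(-t/tau_v) + b exp(-t/tau_p) + eps_r``
    with the fast (viscoelastic-like) timescale ``tau_v`` optionally shared
    across all series, while ``a``, ``b``, the slow plastic timescale
    ``tau_p`` and the residual strain ``eps_r`` vary per series.  The
    ordering constraint ``tau_v < tau_p`` is built into the
    parametrization.
    """

    tau_v: float | np.ndarray  # minutes (scalar if shared)
    a: np.ndarray
    b: np.ndarray
    tau_p: np.ndarray  # minutes, per series
    eps_r: np.ndarray
    residual_norm: float
    converged: bool
    flagged: bool = False
    message: str = ""

    @property
    def tau_v_seconds(self):
        return np.asarray(self.tau_v) * 60.0

    def curve(self, k: int, t):
        t = np.asarray(t)
        tv = self.tau_v if np.isscalar(self.tau_v) else self.tau_v[k]
        return (
            self.a[k] * np.exp(-t / tv)
            + self.b[k] * np.exp(-t / self.tau_p[k])
            + self.eps_r[k]
        )


def fit_double_exponential(
    series_list,
    shared_tau_v: bool = True,
    tau_v_grid=None,
    identifiability_ratio: float = 2.0,
) -> DoubleExponentialFit:
    """Fit ``a exp(-t/tau_v) + b exp(-t/tau_p) + eps_r`` to one or more series.

    ``series_list`` is a sequence of ``(t_minutes, strain)`` pairs or
    :class:`RelaxationSeries`.  With ``shared_tau_v`` a single fast
    timescale is fitted jointly across all series.  Multi-start over a
    log-spaced ``tau_v`` grid guards against local minima; the slow scale
    is parametrized as ``tau_p = tau_v (1 + exp(u))`` which enforces
    ``tau_v < tau_p``.  If the two recovered timescales are closer than
    ``identifiability_ratio`` for any series the fit is flagged.
    """
    data = []
    for s in series_list:
        if isinstance(s, RelaxationSeries):
            data.append((np.asarray(s.t, float), np.asarray(s.strain, float)))
        else:
            t, y = s
            data.append((np.asarray(t, float), np.asarray(y, float)))
    for t, y in data:
        if t.size < 6:
            raise ValueError("need >= 6 points per series")
    n = len(data)
    if not shared_tau_v:
        fits = [
            fit_double_exponential([d], shared_tau_v=True, tau_v_grid=tau_v_grid)
            for d in data
        ]
        return DoubleExponentialFit(
            tau_v=np.array([float(np.atleast_1d(f.tau_v)[0]) for f in fits]),
            a=np.array([f.a[0] for f in fits]),
            b=np.array([f.b[0] for f in fits]),
            tau_p=np.array([f.tau_p[0] for f in fits]),
            eps_r=np.array([f.eps_r[0] for f in fits]),
            residual_norm=float(
                np.sqrt(sum(f.residual_norm**2 for f in fits))
            ),
            converged=all(f.converged for f in fits),
            flagged=any(f.flagged for f in fits),
        )

    t_max = max(t.max() for t, _ in data)
    t_min_pos = min(t[t > 0].min() if (t > 0).any() else t_max for t, _ in data)
    if tau_v_grid is None:
        tau_v_grid = np.geomspace(
            max(t_min_pos / 4, 1e-3), max(t_max / 4, t_min_pos), 6
        )

    def unpack(x):
        tau_v = np.exp(x[0])
        per = x[1:].reshape(n, 4)
        a = per[:, 0]
        b = per[:, 1]
        tau_p = tau_v * (1.0 + np.exp(per[:, 2]))
        eps_r = per[:, 3]
        return tau_v, a, b, tau_p, eps_r

    def resid(x):
        tau_v, a, b, tau_p, eps_r = unpack(x)
        out = []
        for k, (t, y) in enumerate(data):
            out.append(
                a[k] * np.exp(-t / tau_v)
                + b[k] * np.exp(-t / tau_p[k])
                + eps_r[k]
                - y
            )
        return np.concatenate(out)

    best = None
    for tv0 in np.atleast_1d(tau_v_grid):
        x0 = [np.log(tv0)]
        for t, y in data:
            c0 = float(y[-max(2, t.size // 5):].mean())
            amp = float(y[0] - c0)
            x0 += [amp / 2, amp / 2, np.log(9.0), c0]  # tau_p ~ 10 tau_v
        res = scipy.optimize.least_squares(resid, x0=np.asarray(x0), max_nfev=20000)
        if best is None or res.cost < best.cost:
            best = res
    tau_v, a, b, tau_p, eps_r = unpack(best.x)
    flagged = bool(np.any(tau_p < identifiability_ratio * tau_v))
    return DoubleExponentialFit(
        tau_v=float(tau_v),
        a=a.copy(),
        b=b.copy(),
        tau_p=tau_p.copy(),
        eps_r=eps_r.copy(),
        residual_norm=float(np.sqrt(2 * best.cost)),
        converged=bool(best.success),
        flagged=flagged,
        message="tau_v ~ tau_p: components weakly identifiable" if flagged else "",
    )


# -- directional compliance ------------------------------------------------

@dataclass
class ComplianceProbe:
    node: int
    thetas: np.ndarray  # radians
    J: np.ndarray  # compliance per direction (relative units)
    major: float
    minor: float
    orientation: float
    flagged: bool = False

    @property
    def aspect_ratio(self) -> float:
        return self.major / self.minor


def probe_compliance(
    state: NetworkState,
    params: ElasticParams,
    node: int,
    force_magnitude: float = 1.0e-3,
    n_directions: int = 12,
    prefactor: float = 1.0,
    grad_tol: float = 1.0e-9,
    displacement_cap: float = 10.0,
) -> ComplianceProbe:
    """Directional compliance ``J(theta)`` of one node and its ellipse fit.

    A small force of ``force_magnitude`` (default ``1e-3 k a0``, linear
    response) is applied at the node along each of ``n_directions`` evenly
    spaced directions; after re-minimization the compliance is the
    displacement component along the force direction divided by the force,
    times ``prefactor`` (the bead-geometry factor 6 pi a of the optical
    tweezers readout; 1 by default, so J is relative).  The polar points
    ``(J cos, J sin)`` are fitted with a direct least-squares ellipse whose
    axis ratio quantifies local mechanical anisotropy.  Unstable probes
    (displacement beyond ``displacement_cap``) are flagged.
    """
    from skimage.measure import EllipseModel

    if not state.free[node]:
        raise ValueError("probe node lies on a fixed boundary")
    thetas = np.arange(n_directions) * (2 * np.pi / n_directions)
    base = minimize(state, params, grad_tol=grad_tol, warn=False)
    x_ref = base.state.positions[node].copy()
    J = np.empty(n_directions)
    flagged = False
    for k, th in enumerate(thetas):
        f = np.zeros_like(state.positions)
        direction = np.array([np.cos(th), np.sin(th)])
        f[node] = force_magnitude * direction
        res = minimize(
            base.state, params, grad_tol=grad_tol, external_forces=f, warn=False
        )
        disp = res.state.positions[node] - x_ref
        d_par = float(disp @ direction)
        if abs(d_par) > displacement_cap or not res.converged:
            flagged = True
        J[k] = prefactor * d_par / force_magnitude
    pts = np.column_stack([J * np.cos(thetas), J * np.sin(thetas)])
    try:  # scikit-image >= 0.26 constructor API
        em = EllipseModel.from_estimate(pts)
        ok = bool(em)
        if ok:
            a, b = (float(v) for v in em.axis_lengths)
            ori = float(em.theta)
    except AttributeError:  # older scikit-image
        em = EllipseModel()
        ok = em.estimate(pts)
        if ok:
            _, _, a, b, ori = em.params
    if not ok:
        return ComplianceProbe(
            node=node, thetas=thetas, J=J,
            major=float("nan"), minor=float("nan"), orientation=float("nan"),
            flagged=True,
        )
    major, minor = max(a, b), min(a, b)
    return ComplianceProbe(
        node=int(node),
        thetas=thetas,
        J=J,
        major=float(major),
        minor=float(minor),
        orientation=float(ori),
        flagged=flagged,
    )
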