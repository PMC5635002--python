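"""Fused energy/gradient kernel, JIT-compiled when numba is available.

The quasistatic protocols spend nearly all their time evaluating the
total elastic energy and its gradient inside the minimizer, so this one
hot loop is implemented in compiled form.  The pure-numpy implementations
in :mod:`fiberplast.mechanics` remain the reference (and the fallback
when numba is missing); equality of the two paths is covered by tests.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a soft dependency
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True, fastmath=False)
def _energy_grad_core(
    pos,
    bi,
    bj,
    rest,
    shift,
    k,
    normalize,
    kappa,
    ha,
    hb,
    hc,
    su,
    sv,
    grad,
):
    es = 0.0
    for m in range(bi.shape[0]):
        i = bi[m]
        j = bj[m]
        dx = pos[j, 0] + shift[m, 0] - pos[i, 0]
        dy = pos[j, 1] + shift[m, 1] - pos[i, 1]
        length = np.sqrt(dx * dx + dy * dy)
        l0 = rest[m]
        coef = k / l0 if normalize else k
        dl = length - l0
        es += 0.5 * coef * dl * dl
        if length > 0.0:
            f = coef * dl / length
            fx = f * dx
            fy = f * dy
            grad[j, 0] += fx
            grad[j, 1] += fy
            grad[i, 0] -= fx
            grad[i, 1] -= fy
    eb = 0.0
    if kappa > 0.0:
        for h in range(ha.shape[0]):
            a = ha[h]
            b = hb[h]
            c = hc[h]
            ux = pos[b, 0] + su[h, 0] - pos[a, 0]
            uy = pos[b, 1] + su[h, 1] - pos[a, 1]
            vx = pos[c, 0] + sv[h, 0] - pos[b, 0]
            vy = pos[c, 1] + sv[h, 1] - pos[b, 1]
            cross = ux * vy - uy * vx
            dot = ux * vx + uy * vy
            theta = np.arctan2(cross, dot)
            eb += 0.5 * kappa * theta * theta
            w = kappa * theta
            u2 = ux * ux + uy * uy
            v2 = vx * vx + vy * vy
            if u2 <= 0.0 or v2 <= 0.0:  # degenerate hinge: no restoring torque
                continue
            inv_u2 = 1.0 / u2
            inv_v2 = 1.0 / v2
            gux = w * uy * inv_u2
            guy = -w * ux * inv_u2
            gvx = -w * vy * inv_v2
            gvy = w * vx * inv_v2
            grad[a, 0] -= gux
            grad[a, 1] -= guy
            grad[b, 0] += gux - gvx
            grad[b, 1] += guy - gvy
            grad[c, 0] += gvx
            grad[c, 1] += gvy
    return es, eb


@njit(cache=True, fastmath=False)
def fire_minimize(
    pos,
    free,
    bi,
    bj,
    rest,
    shift,
    k,
    normalize,
    kappa,
    ha,
    hb,
    hc,
    su,
    sv,
    gtol,
    max_steps,
):
    """FIRE quasistatic relaxation over the free nodes, in place.

    Fast inertial relaxation engine with the standard schedule
    (alpha = 0.1, f_inc = 1.1, f_dec = 0.5, N_min = 5); time step capped
    well below the stiff-bond stability limit.  Returns
    ``(n_steps, max_force)``; converged when ``max_force <= gtol`` over
    the free nodes.
    """
    n = pos.shape[0]
    v = np.zeros((n, 2))
    grad = np.zeros((n, 2))
    dt = 0.02
    dt_max = 0.12
    alpha = 0.1
    n_pos = 0
    fmax = 1.0e30
    step = 0
    while step < max_steps:
        step += 1
        grad[:] = 0.0
        _energy_grad_core(
            pos, bi, bj, rest, shift, k, normalize, kappa,
            ha, hb, hc, su, sv, grad,
        )
        # F = -grad on free nodes; frozen nodes keep v = 0
        power = 0.0
        fnorm2 = 0.0
        vnorm2 = 0.0
        fmax = 0.0
        for i in range(n):
            if free[i]:
                fx = -grad[i, 0]
                fy = -grad[i, 1]
                power += fx * v[i, 0] + fy * v[i, 1]
                fnorm2 += fx * fx + fy * fy
                vnorm2 += v[i, 0] * v[i, 0] + v[i, 1] * v[i, 1]
                af = abs(fx)
                if abs(fy) > af:
                    af = abs(fy)
                if af > fmax:
                    fmax = af
        if fmax <= gtol:
            break
        if power > 0.0:
            n_pos += 1
            if fnorm2 > 0.0:
                mix = alpha * np.sqrt(vnorm2 / fnorm2)
                for i in range(n):
                    if free[i]:
                        v[i, 0] = (1.0 - alpha) * v[i, 0] - mix * grad[i, 0]
                        v[i, 1] = (1.0 - alpha) * v[i, 1] - mix * grad[i, 1]
            if n_pos > 5:
                dt = min(dt * 1.1, dt_max)
                alpha *= 0.99
        else:
            n_pos = 0
            dt *= 0.5
            alpha = 0.1
            for i in range(n):
                v[i, 0] = 0.0
                v[i, 1] = 0.0
        for i in range(n):
            if free[i]:
                v[i, 0] -= dt * grad[i, 0]
                v[i, 1] -= dt * grad[i, 1]
                pos[i, 0] += dt * v[i, 0]
                pos[i, 1] += dt * v[i, 1]
    return step, fmax


def energy_and_gradient_fused(positions, bonds, rest, shifts, k, normalize, kappa, hinges):
    """Stretch + bend energy and full position-space gradient.

    Returns ``(e_stretch, e_bend, grad)``; ``grad`` is freshly allocated.
    The bending prefactor assumes unit lattice spacing (kappa / a0 with
    a0 = 1), matching the reference implementation.
    """
    ha, hb, hc, su, sv = hinges
    grad = np.zeros_like(positions)
    es, eb = _energy_grad_core(
        positions,
        np.ascontiguousarray(bonds[:, 0]),
        np.ascontiguousarray(bonds[:, 1]),
        rest,
        shifts,
        float(k),
        bool(normalize),
        float(kappa),
        ha,
        hb,
        hc,
        su,
        sv,
        grad,
    )
    return es, eb, grad
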