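"""Numba position integrator for the regime-switching random walk.

Separated so the heading/steering/reflection loop — the only part of the
simulator that cannot be vectorized (heading feedback on position) — is
compiled once and stays free of Python-object overhead.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _wrap(a):
    while a > np.pi:
        a -= 2 * np.pi
    while a <= -np.pi:
        a += 2 * np.pi
    return a


@njit(cache=True)
def _nearest_boundary(x, y, vx, vy):
    """Nearest point on the polygon boundary to (x, y)."""
    m = len(vx)
    best = 1e300
    bx = x
    by = y
    for e in range(m):
        ax, ay = vx[e], vy[e]
        cx, cy = vx[(e + 1) % m], vy[(e + 1) % m]
        ex, ey = cx - ax, cy - ay
        L2 = ex * ex + ey * ey
        t = ((x - ax) * ex + (y - ay) * ey) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        px, py = ax + t * ex, ay + t * ey
        d = (x - px) ** 2 + (y - py) ** 2
        if d < best:
            best = d
            bx, by = px, py
    return bx, by


@njit(cache=True)
def _inside(x, y, vx, vy):
    """Point-in-convex-CCW-polygon via edge cross products."""
    m = len(vx)
    for e in range(m):
        ax, ay = vx[e], vy[e]
        cx, cy = vx[(e + 1) % m], vy[(e + 1) % m]
        if (cx - ax) * (y - ay) - (cy - ay) * (x - ax) < 0.0:
            return False
    return True


@njit(cache=True)
def integrate(x0, y0, theta0, steps, turns, wall_pull, gain, vx, vy, cx, cy):
    """Sequential position update with wall steering and reflection.

    Per frame: steer the heading toward the nearest wall in proportion to
    the active mode's wall-attraction weight, add the von Mises turn
    noise, advance by the drawn step length, and reflect off any wall that
    would be crossed.  (cx, cy) is the tank centroid used as a fallback
    target if reflection fails in a corner.
    """
    n = len(steps)
    xs = np.empty(n)
    ys = np.empty(n)
    x, y, th = x0, y0, theta0
    for i in range(n):
        if wall_pull[i] > 0.0:
            bx, by = _nearest_boundary(x, y, vx, vy)
            bearing = np.arctan2(by - y, bx - x)
            th = th + wall_pull[i] * gain * _wrap(bearing - th)
        th = _wrap(th + turns[i])
        nx = x + steps[i] * np.cos(th)
        ny = y + steps[i] * np.sin(th)
        if not _inside(nx, ny, vx, vy):
            m = len(vx)
            for _ in range(3):
                fixed = True
                for e in range(m):
                    ax, ay = vx[e], vy[e]
                    bx2, by2 = vx[(e + 1) % m], vy[(e + 1) % m]
                    ex, ey = bx2 - ax, by2 - ay
                    L = np.sqrt(ex * ex + ey * ey)
                    # inward unit normal of a CCW edge
                    nxu, nyu = -ey / L, ex / L
                    s = (nx - ax) * nxu + (ny - ay) * nyu
                    if s < 0.0:
                        nx -= 2.0 * s * nxu
                        ny -= 2.0 * s * nyu
                        th = _wrap(2.0 * np.arctan2(ey, ex) - th)
                        fixed = False
                if fixed and _inside(nx, ny, vx, vy):
                    break
            if not _inside(nx, ny, vx, vy):
                # pathological corner: retreat toward the centroid
                nx = x + 0.5 * (cx - x) * 0.01
                ny = y + 0.5 * (cy - y) * 0.01
                th = np.arctan2(cy - ny, cx - nx)
        x, y = nx, ny
        xs[i] = x
        ys[i] = y
    return xs, ys
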