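"""Numba-compiled hot loops shared by the field and diffusion engines.

Every Monte Carlo approach spends essentially all of its time summing
per-vessel analytic field offsets or testing point/vessel membership over
ensembles of spins, so these two loops are JIT-compiled.  All other code is
plain numpy/scipy.

Conventions: points and vessel geometry are float64 arrays in um; periods
holds the per-axis wrap length for the minimum-image convention (0 disables
wrapping on that axis); field coefficients are pre-reduced per vessel so the
inner loop only evaluates the radial/angular factors of the cylinder dipole
field.
"""

import numpy as np
from numba import njit


@njit(cache=True, fastmath=True)
def sum_cylinder_offsets(pts, anchors, axes, radii2, icoef, ecoef, bperp, out):
    """Summed cylinder field offsets (T) at each point.

    For vessel v with unit axis n_v: a point at perpendicular offset r from
    the axis contributes icoef[v] if r^2 <= radii2[v], and otherwise
    ecoef[v] * (R^2/r^2) * cos(2*phi), with phi measured from bperp[v] (the
    unit projection of that vessel's B0 direction onto its transverse plane).
    icoef/ecoef carry all constant factors, including Delta-chi, B0 and the
    sin^2(theta) / (3cos^2(theta)-1) orientation terms.
    """
    n_pts = pts.shape[0]
    n_v = anchors.shape[0]
    for i in range(n_pts):
        tot = 0.0
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        for v in range(n_v):
            dx = px - anchors[v, 0]
            dy = py - anchors[v, 1]
            dz = pz - anchors[v, 2]
            t = dx * axes[v, 0] + dy * axes[v, 1] + dz * axes[v, 2]
            rx = dx - t * axes[v, 0]
            ry = dy - t * axes[v, 1]
            rz = dz - t * axes[v, 2]
            r2 = rx * rx + ry * ry + rz * rz
            if r2 <= radii2[v]:
                tot += icoef[v]
            elif ecoef[v] != 0.0:
                dot = rx * bperp[v, 0] + ry * bperp[v, 1] + rz * bperp[v, 2]
                tot += ecoef[v] * (radii2[v] / r2) * (2.0 * dot * dot / r2 - 1.0)
        out[i] = tot


@njit(cache=True, fastmath=True)
def sum_cylinder_offsets_wrapped(pts, anchors, axes, radii2, icoef, ecoef,
                                 bperp, periods, out):
    """As :func:`sum_cylinder_offsets`, with minimum-image displacement wrap."""
    n_pts = pts.shape[0]
    n_v = anchors.shape[0]
    for i in range(n_pts):
        tot = 0.0
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        for v in range(n_v):
            dx = px - anchors[v, 0]
            dy = py - anchors[v, 1]
            dz = pz - anchors[v, 2]
            if periods[0] > 0.0:
                dx -= periods[0] * np.floor(dx / periods[0] + 0.5)
            if periods[1] > 0.0:
                dy -= periods[1] * np.floor(dy / periods[1] + 0.5)
            if periods[2] > 0.0:
                dz -= periods[2] * np.floor(dz / periods[2] + 0.5)
            t = dx * axes[v, 0] + dy * axes[v, 1] + dz * axes[v, 2]
            rx = dx - t * axes[v, 0]
            ry = dy - t * axes[v, 1]
            rz = dz - t * axes[v, 2]
            r2 = rx * rx + ry * ry + rz * rz
            if r2 <= radii2[v]:
                tot += icoef[v]
            elif ecoef[v] != 0.0:
                dot = rx * bperp[v, 0] + ry * bperp[v, 1] + rz * bperp[v, 2]
                tot += ecoef[v] * (radii2[v] / r2) * (2.0 * dot * dot / r2 - 1.0)
        out[i] = tot


@njit(cache=True, fastmath=True)
def inside_any_cylinder(pts, anchors, axes, radii2, periods, out):
    """Boolean intravascular test against a set of (infinite) cylinders."""
    n_pts = pts.shape[0]
    n_v = anchors.shape[0]
    for i in range(n_pts):
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        hit = False
        for v in range(n_v):
            dx = px - anchors[v, 0]
            dy = py - anchors[v, 1]
            dz = pz - anchors[v, 2]
            if periods[0] > 0.0:
                dx -= periods[0] * np.floor(dx / periods[0] + 0.5)
            if periods[1] > 0.0:
                dy -= periods[1] * np.floor(dy / periods[1] + 0.5)
            if periods[2] > 0.0:
                dz -= periods[2] * np.floor(dz / periods[2] + 0.5)
            t = dx * axes[v, 0] + dy * axes[v, 1] + dz * axes[v, 2]
            rx = dx - t * axes[v, 0]
            ry = dy - t * axes[v, 1]
            rz = dz - t * axes[v, 2]
            if rx * rx + ry * ry + rz * rz <= radii2[v]:
                hit = True
                break
        out[i] = hit


@njit(cache=True, fastmath=True)
def inside_any_segment(pts, ends_a, ends_b, radii2, out):
    """Boolean intravascular test against finite capped-cylinder segments."""
    n_pts = pts.shape[0]
    n_s = ends_a.shape[0]
    for i in range(n_pts):
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        hit = False
        for s in range(n_s):
            ax = ends_a[s, 0]
            ay = ends_a[s, 1]
            az = ends_a[s, 2]
            vx = ends_b[s, 0] - ax
            vy = ends_b[s, 1] - ay
            vz = ends_b[s, 2] - az
            wx = px - ax
            wy = py - ay
            wz = pz - az
            vv = vx * vx + vy * vy + vz * vz
            t = (wx * vx + wy * vy + wz * vz) / vv
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
            dx = wx - t * vx
            dy = wy - t * vy
            dz = wz - t * vz
            if dx * dx + dy * dy + dz * dz <= radii2[s]:
                hit = True
                break
        out[i] = hit


@njit(cache=True, fastmath=True)
def min_distance_to_segments(p, ends_a, ends_b):
    """Smallest distance from point p (3,) to any segment axis."""
    best = 1e300
    for s in range(ends_a.shape[0]):
        ax = ends_a[s, 0]
        ay = ends_a[s, 1]
        az = ends_a[s, 2]
        vx = ends_b[s, 0] - ax
        vy = ends_b[s, 1] - ay
        vz = ends_b[s, 2] - az
        wx = p[0] - ax
        wy = p[1] - ay
        wz = p[2] - az
        vv = vx * vx + vy * vy + vz * vz
        if vv == 0.0:
            t = 0.0
        else:
            t = (wx * vx + wy * vy + wz * vz) / vv
            if t < 0.0:
                t = 0.0
            elif t > 1.0:
                t = 1.0
        dx = wx - t * vx
        dy = wy - t * vy
        dz = wz - t * vz
        d2 = dx * dx + dy * dy + dz * dz
        if d2 < best:
            best = d2
    return np.sqrt(best)


@njit(cache=True, fastmath=True)
def offsets_and_inside(pts, anchors, axes, radii2, icoef, ecoef, bperp,
                       periods, out, inside):
    """Fused field-sum + intravascular test (one pass over vessels).

    The Monte Carlo engines need both quantities at every proposed spin
    position each step; fusing them halves the dominant cost.
    """
    n_pts = pts.shape[0]
    n_v = anchors.shape[0]
    wrap_x = periods[0] > 0.0
    wrap_y = periods[1] > 0.0
    wrap_z = periods[2] > 0.0
    for i in range(n_pts):
        tot = 0.0
        hit = False
        px = pts[i, 0]
        py = pts[i, 1]
        pz = pts[i, 2]
        for v in range(n_v):
            dx = px - anchors[v, 0]
            dy = py - anchors[v, 1]
            dz = pz - anchors[v, 2]
            if wrap_x:
                dx -= periods[0] * np.floor(dx / periods[0] + 0.5)
            if wrap_y:
                dy -= periods[1] * np.floor(dy / periods[1] + 0.5)
            if wrap_z:
                dz -= periods[2] * np.floor(dz / periods[2] + 0.5)
            t = dx * axes[v, 0] + dy * axes[v, 1] + dz * axes[v, 2]
            rx = dx - t * axes[v, 0]
            ry = dy - t * axes[v, 1]
            rz = dz - t * axes[v, 2]
            r2 = rx * rx + ry * ry + rz * rz
            if r2 <= radii2[v]:
                tot += icoef[v]
                hit = True
            elif ecoef[v] != 0.0:
                dot = rx * bperp[v, 0] + ry * bperp[v, 1] + rz * bperp[v, 2]
                tot += ecoef[v] * (radii2[v] / r2) * (2.0 * dot * dot / r2 - 1.0)
        out[i] = tot
        inside[i] = hit
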