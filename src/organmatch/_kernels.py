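"""Compiled inner loops for point/surface queries.

The optimizer evaluates the cost a few hundred times per fraction, and
every evaluation needs all point-to-triangle distances plus a winding
number per vertex.  These scalar kernels are numba-compiled; the numpy
implementations in :mod:`organmatch.geometry` remain the portable
fallback and the reference in tests.
"""

from __future__ import annotations

import math

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _closest_sq(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Squared distance from one point to one triangle (Voronoi regions)."""
    abx, aby, abz = bx - ax, by - ay, bz - az
    acx, acy, acz = cx - ax, cy - ay, cz - az
    apx, apy, apz = px - ax, py - ay, pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return apx * apx + apy * apy + apz * apz
    bpx, bpy, bpz = px - bx, py - by, pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bpx * bpx + bpy * bpy + bpz * bpz
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        den = d1 - d3
        v = d1 / den if den != 0.0 else 0.0
        qx, qy, qz = apx - v * abx, apy - v * aby, apz - v * abz
        return qx * qx + qy * qy + qz * qz
    cpx, cpy, cpz = px - cx, py - cy, pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cpx * cpx + cpy * cpy + cpz * cpz
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        den = d2 - d6
        w = d2 / den if den != 0.0 else 0.0
        qx, qy, qz = apx - w * acx, apy - w * acy, apz - w * acz
        return qx * qx + qy * qy + qz * qz
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        den = (d4 - d3) + (d5 - d6)
        w = (d4 - d3) / den if den != 0.0 else 0.0
        bcx, bcy, bcz = cx - bx, cy - by, cz - bz
        qx, qy, qz = bpx - w * bcx, bpy - w * bcy, bpz - w * bcz
        return qx * qx + qy * qy + qz * qz
    den = va + vb + vc
    if den == 0.0:
        return apx * apx + apy * apy + apz * apz
    v = vb / den
    w = vc / den
    qx = apx - v * abx - w * acx
    qy = apy - v * aby - w * acy
    qz = apz - v * abz - w * acz
    return qx * qx + qy * qy + qz * qz


@njit(cache=True)
def min_distances(points, tri):
    """Minimum unsigned distance from each point to any triangle."""
    n = points.shape[0]
    m = tri.shape[0]
    out = np.empty(n)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        best = 1e300
        for j in range(m):
            d = _closest_sq(
                px, py, pz,
                tri[j, 0, 0], tri[j, 0, 1], tri[j, 0, 2],
                tri[j, 1, 0], tri[j, 1, 1], tri[j, 1, 2],
                tri[j, 2, 0], tri[j, 2, 1], tri[j, 2, 2],
            )
            if d < best:
                best = d
        out[i] = math.sqrt(best)
    return out


@njit(cache=True)
def winding_numbers(points, tri):
    """Generalized winding number of each point w.r.t. the triangle soup
    (sum of signed solid angles / 4π, van Oosterom-Strackee)."""
    n = points.shape[0]
    m = tri.shape[0]
    out = np.empty(n)
    for i in range(n):
        px, py, pz = points[i, 0], points[i, 1], points[i, 2]
        total = 0.0
        for j in range(m):
            ax, ay, az = tri[j, 0, 0] - px, tri[j, 0, 1] - py, tri[j, 0, 2] - pz
            bx, by, bz = tri[j, 1, 0] - px, tri[j, 1, 1] - py, tri[j, 1, 2] - pz
            cx, cy, cz = tri[j, 2, 0] - px, tri[j, 2, 1] - py, tri[j, 2, 2] - pz
            la = math.sqrt(ax * ax + ay * ay + az * az)
            lb = math.sqrt(bx * bx + by * by + bz * bz)
            lc = math.sqrt(cx * cx + cy * cy + cz * cz)
            # a · (b × c)
            num = (
                ax * (by * cz - bz * cy)
                + ay * (bz * cx - bx * cz)
                + az * (bx * cy - by * cx)
            )
            den = (
                la * lb * lc
                + (ax * bx + ay * by + az * bz) * lc
                + (bx * cx + by * cy + bz * cz) * la
                + (ax * cx + ay * cy + az * cz) * lb
            )
            total += math.atan2(num, den)
        out[i] = total / (2.0 * math.pi)
    return out
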