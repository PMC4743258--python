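"""Numba inner loops for chain generation and half-chain pairing.

These kernels mirror the mid-step frame algebra of :mod:`dnacyc.geometry`
(which stays in plain numpy precisely so the two routes can be checked
against each other) but keep everything in scalar registers:

* ``end_frames``          — terminal frame of each chain in a batch,
* ``chain_normals``       — per-base-pair normals (tangents) of each chain,
* ``pair_counts_grid``    — closure tallies over all M^2 half-chain pairs
                            using an exact uniform-grid prefilter,
* ``pair_counts_brute``   — the same tallies by exhaustive pairing.

Trigonometry is reduced to two sincos calls per step: the bend phase enters
through cos(phi) = roll/Gamma, sin(phi) = tilt/Gamma, and the full bend
angle through its half via double-angle identities.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

# Cell-key packing: 21 bits per signed grid index (|index| < 2**20).
_KEY_OFFSET = 1 << 20


@njit(cache=False)
def _step_matrices(tilt, roll, twist, shift, slide, rise):
    """Rotation R (row-major scalars) and mid-frame translation of one step."""
    gamma = math.sqrt(tilt * tilt + roll * roll)
    if gamma > 1e-300:
        cp = roll / gamma
        sp = tilt / gamma
    else:
        cp = 1.0
        sp = 0.0
    ct = math.cos(0.5 * twist)
    st = math.sin(0.5 * twist)
    chg = math.cos(0.5 * gamma)
    shg = math.sin(0.5 * gamma)
    cg = chg * chg - shg * shg
    sg = 2.0 * shg * chg
    # a = twist/2 - phi, b = twist/2 + phi
    ca = ct * cp + st * sp
    sa = st * cp - ct * sp
    cb = ct * cp - st * sp
    sb = st * cp + ct * sp
    # R = Rz(a) @ Ry(gamma) @ Rz(b)
    r00 = ca * cg * cb - sa * sb
    r01 = -ca * cg * sb - sa * cb
    r02 = ca * sg
    r10 = sa * cg * cb + ca * sb
    r11 = -sa * cg * sb + ca * cb
    r12 = sa * sg
    r20 = -sg * cb
    r21 = sg * sb
    r22 = cg
    # Rm = Rz(a) @ Ry(gamma/2) @ Rz(phi); t = Rm @ (shift, slide, rise)
    m00 = ca * chg * cp - sa * sp
    m01 = -ca * chg * sp - sa * cp
    m02 = ca * shg
    m10 = sa * chg * cp + ca * sp
    m11 = -sa * chg * sp + ca * cp
    m12 = sa * shg
    m20 = -shg * cp
    m21 = shg * sp
    m22 = chg
    tx = m00 * shift + m01 * slide + m02 * rise
    ty = m10 * shift + m11 * slide + m12 * rise
    tz = m20 * shift + m21 * slide + m22 * rise
    return r00, r01, r02, r10, r11, r12, r20, r21, r22, tx, ty, tz


@njit(cache=False)
def end_frames(params, origins, triads):
    """Terminal frame of each chain.

    ``params``: (B, n_steps, 6) sampled step coordinates, radians / Å.
    Fills ``origins`` (B, 3) and ``triads`` (B, 3, 3); the first frame of
    every chain is the canonical frame at the origin.
    """
    B, n, _ = params.shape
    for c in range(B):
        t00 = 1.0; t01 = 0.0; t02 = 0.0
        t10 = 0.0; t11 = 1.0; t12 = 0.0
        t20 = 0.0; t21 = 0.0; t22 = 1.0
        ox = 0.0; oy = 0.0; oz = 0.0
        for k in range(n):
            (r00, r01, r02, r10, r11, r12, r20, r21, r22, tx, ty, tz) = _step_matrices(
                params[c, k, 0], params[c, k, 1], params[c, k, 2],
                params[c, k, 3], params[c, k, 4], params[c, k, 5],
            )
            ox += t00 * tx + t01 * ty + t02 * tz
            oy += t10 * tx + t11 * ty + t12 * tz
            oz += t20 * tx + t21 * ty + t22 * tz
            u00 = t00 * r00 + t01 * r10 + t02 * r20
            u01 = t00 * r01 + t01 * r11 + t02 * r21
            u02 = t00 * r02 + t01 * r12 + t02 * r22
            u10 = t10 * r00 + t11 * r10 + t12 * r20
            u11 = t10 * r01 + t11 * r11 + t12 * r21
            u12 = t10 * r02 + t11 * r12 + t12 * r22
            u20 = t20 * r00 + t21 * r10 + t22 * r20
            u21 = t20 * r01 + t21 * r11 + t22 * r21
            u22 = t20 * r02 + t21 * r12 + t22 * r22
            t00 = u00; t01 = u01; t02 = u02
            t10 = u10; t11 = u11; t12 = u12
            t20 = u20; t21 = u21; t22 = u22
        origins[c, 0] = ox; origins[c, 1] = oy; origins[c, 2] = oz
        triads[c, 0, 0] = t00; triads[c, 0, 1] = t01; triads[c, 0, 2] = t02
        triads[c, 1, 0] = t10; triads[c, 1, 1] = t11; triads[c, 1, 2] = t12
        triads[c, 2, 0] = t20; triads[c, 2, 1] = t21; triads[c, 2, 2] = t22


@njit(cache=False)
def chain_normals(params, normals):
    """Base-pair normals along each chain.

    ``params``: (B, n_steps, 6); fills ``normals`` (B, n_steps + 1, 3), the
    third triad column of every frame (frame 1 is canonical: normal e_z).
    """
    B, n, _ = params.shape
    for c in range(B):
        t00 = 1.0; t01 = 0.0; t02 = 0.0
        t10 = 0.0; t11 = 1.0; t12 = 0.0
        t20 = 0.0; t21 = 0.0; t22 = 1.0
        normals[c, 0, 0] = 0.0; normals[c, 0, 1] = 0.0; normals[c, 0, 2] = 1.0
        for k in range(n):
            (r00, r01, r02, r10, r11, r12, r20, r21, r22, tx, ty, tz) = _step_matrices(
                params[c, k, 0], params[c, k, 1], params[c, k, 2],
                params[c, k, 3], params[c, k, 4], params[c, k, 5],
            )
            u00 = t00 * r00 + t01 * r10 + t02 * r20
            u01 = t00 * r01 + t01 * r11 + t02 * r21
            u02 = t00 * r02 + t01 * r12 + t02 * r22
            u10 = t10 * r00 + t11 * r10 + t12 * r20
            u11 = t10 * r01 + t11 * r11 + t12 * r21
            u12 = t10 * r02 + t11 * r12 + t12 * r22
            u20 = t20 * r00 + t21 * r10 + t22 * r20
            u21 = t20 * r01 + t21 * r11 + t22 * r21
            u22 = t20 * r02 + t21 * r12 + t22 * r22
            t00 = u00; t01 = u01; t02 = u02
            t10 = u10; t11 = u11; t12 = u12
            t20 = u20; t21 = u21; t22 = u22
            normals[c, k + 1, 0] = t02
            normals[c, k + 1, 1] = t12
            normals[c, k + 1, 2] = t22


@njit(cache=False, inline="always")
def _pair_hits(qx, qy, qz, px, py, pz, R1, T2, j, rc2, cg_min, cp_min):
    """Closure test for one (first half i, second half j) pair.

    Returns 0 (no r-hit), 1 (r-hit), 2 (r- and gamma-hit), 3 (full closure).
    ``(qx,qy,qz)`` is -R_i^T o_i, ``(px,py,pz)`` the second half's end origin
    in the junction frame, so the end-to-end distance is |p - q|.
    """
    dx = px - qx
    dy = py - qy
    dz = pz - qz
    if dx * dx + dy * dy + dz * dz >= rc2:
        return 0
    # terminal triad = R1 @ T2; normal_N = R1 @ T2[:, 2]
    a02 = T2[j, 0, 2]; a12 = T2[j, 1, 2]; a22 = T2[j, 2, 2]
    nz = R1[2, 0] * a02 + R1[2, 1] * a12 + R1[2, 2] * a22
    if nz <= cg_min:  # cos(gamma) = e_z . normal_N
        return 1
    nx = R1[0, 0] * a02 + R1[0, 1] * a12 + R1[0, 2] * a22
    ny = R1[1, 0] * a02 + R1[1, 1] * a12 + R1[1, 2] * a22
    # short axis of the terminal frame: x_N = R1 @ T2[:, 0]
    a00 = T2[j, 0, 0]; a10 = T2[j, 1, 0]; a20 = T2[j, 2, 0]
    xx = R1[0, 0] * a00 + R1[0, 1] * a10 + R1[0, 2] * a20
    xy = R1[1, 0] * a00 + R1[1, 1] * a10 + R1[1, 2] * a20
    xz = R1[2, 0] * a00 + R1[2, 1] * a10 + R1[2, 2] * a20
    # average normal between e_z and n_N (safe: nz > 0.86 here)
    bx = nx; by = ny; bz = nz + 1.0
    bn = math.sqrt(bx * bx + by * by + bz * bz)
    bx /= bn; by /= bn; bz /= bn
    # project e_x and x_N onto the plane perpendicular to the average normal
    p1x = 1.0 - bx * bx; p1y = -bx * by; p1z = -bx * bz
    d2 = xx * bx + xy * by + xz * bz
    p2x = xx - d2 * bx; p2y = xy - d2 * by; p2z = xz - d2 * bz
    n1 = math.sqrt(p1x * p1x + p1y * p1y + p1z * p1z)
    n2 = math.sqrt(p2x * p2x + p2y * p2y + p2z * p2z)
    if n1 < 1e-12 or n2 < 1e-12:
        return 2
    cphi = (p1x * p2x + p1y * p2y + p1z * p2z) / (n1 * n2)
    if cphi > cp_min:
        return 3
    return 2


@njit(cache=False)
def pair_counts_grid(q, R1, p_sorted, T2_sorted, keys_sorted, rc, cg_min, cp_min):
    """Closure tallies over all M^2 half-chain pairs via a uniform grid.

    ``q`` (M, 3): per first half, the point -R_i^T o_i; a pair closes within
    ``rc`` iff the second half's end origin lies within ``rc`` of it.
    Second-half arrays are pre-sorted by packed grid key (cell size = rc),
    so every candidate lies in one of the 27 neighbouring cells — the
    prefilter is exact, not approximate.  Returns (n_r, n_gamma, n_phi).
    """
    M = q.shape[0]
    rc2 = rc * rc
    n_r = 0
    n_g = 0
    n_p = 0
    n2 = p_sorted.shape[0]
    for i in range(M):
        qx = q[i, 0]; qy = q[i, 1]; qz = q[i, 2]
        ix = np.int64(math.floor(qx / rc))
        iy = np.int64(math.floor(qy / rc))
        iz = np.int64(math.floor(qz / rc))
        Ri = R1[i]
        for dx in range(-1, 2):
            for dy in range(-1, 2):
                base = ((ix + dx + _KEY_OFFSET) << 42) + ((iy + dy + _KEY_OFFSET) << 21)
                for dz in range(-1, 2):
                    key = base + (iz + dz + _KEY_OFFSET)
                    # binary search for the key's range in the sorted array
                    lo = np.searchsorted(keys_sorted, key, side="left")
                    if lo >= n2 or keys_sorted[lo] != key:
                        continue
                    hi = np.searchsorted(keys_sorted, key, side="right")
                    for j in range(lo, hi):
                        h = _pair_hits(
                            qx, qy, qz,
                            p_sorted[j, 0], p_sorted[j, 1], p_sorted[j, 2],
                            Ri, T2_sorted, j, rc2, cg_min, cp_min,
                        )
                        if h >= 1:
                            n_r += 1
                            if h >= 2:
                                n_g += 1
                                if h == 3:
                                    n_p += 1
    return n_r, n_g, n_p


@njit(cache=False)
def pair_counts_brute(q, R1, p, T2, rc, cg_min, cp_min):
    """Exhaustive M x M pairing; reference for the grid prefilter."""
    M = q.shape[0]
    rc2 = rc * rc
    n_r = 0
    n_g = 0
    n_p = 0
    for i in range(M):
        qx = q[i, 0]; qy = q[i, 1]; qz = q[i, 2]
        Ri = R1[i]
        for j in range(p.shape[0]):
            h = _pair_hits(qx, qy, qz, p[j, 0], p[j, 1], p[j, 2], Ri, T2, j, rc2, cg_min, cp_min)
            if h >= 1:
                n_r += 1
                if h >= 2:
                    n_g += 1
                    if h == 3:
                        n_p += 1
    return n_r, n_g, n_p


def grid_keys(points: np.ndarray, cell: float) -> np.ndarray:
    """Packed int64 grid key of each 3D point (cell size = capture radius)."""
    idx = np.floor(points / cell).astype(np.int64)
    if np.any(np.abs(idx) >= _KEY_OFFSET):  # pragma: no cover - unreachable at DNA scales
        raise OverflowError("grid index exceeds key packing range")
    return ((idx[:, 0] + _KEY_OFFSET) << 42) + ((idx[:, 1] + _KEY_OFFSET) << 21) + (
        idx[:, 2] + _KEY_OFFSET
    )
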