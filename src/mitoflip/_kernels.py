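"""Compiled inner loops for surface Brownian dynamics.

The kernel mirrors the vectorised numpy operations in :mod:`mitoflip.engine`
(tangent-plane step, polyline projection, lipid-domain rule, permeable plane,
obstacle collisions, bleaching) in one scalar loop per particle per time
step.  The numpy implementations remain the reference; agreement between the
two paths is asserted in the test suite on statistical observables.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _member(x, intervals):
    for j in range(intervals.shape[0]):
        if intervals[j, 0] <= x <= intervals[j, 1]:
            return True
    return False


@njit(cache=True, inline="always")
def _project_local(X, R, x0, r0, idx0, window):
    """Closest point on the profile polyline near vertex idx0."""
    nv = X.shape[0]
    j0 = idx0 - window
    j1 = idx0 + window
    if j0 < 0:
        j0 = 0
    if j1 > nv - 1:
        j1 = nv - 1
    best = j0
    bd = 1e300
    for j in range(j0, j1 + 1):
        dxx = X[j] - x0
        drr = R[j] - r0
        d = dxx * dxx + drr * drr
        if d < bd:
            bd = d
            best = j
    bx = X[best]
    br = R[best]
    bd2 = bd
    sbest = best if best <= nv - 2 else nv - 2
    for s in range(best - 1, best + 1):
        if s < 0 or s > nv - 2:
            continue
        dx = X[s + 1] - X[s]
        dr = R[s + 1] - R[s]
        L2 = dx * dx + dr * dr
        if L2 <= 0.0:
            continue
        t = ((x0 - X[s]) * dx + (r0 - R[s]) * dr) / L2
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
        px = X[s] + t * dx
        pr = R[s] + t * dr
        d = (px - x0) ** 2 + (pr - r0) ** 2
        if d < bd2:
            bd2 = d
            bx = px
            br = pr
            sbest = s
    if br < 0.0:
        br = 0.0
    return bx, br, sbest


@njit(cache=True)
def flip_surface_kernel(X, R, vertex_spacing,
                        pos, hint, unbleached,
                        D_out, D_in, dt, n_steps, sample_every,
                        intervals, p_in_eff, p_out,
                        has_plane, plane_pos, plane_p,
                        obst, contact_r,
                        spot_cx, spot_cy, spot_half, spot_rad, p_bleach,
                        lobe_lo, lobe_hi, rng,
                        mother_counts, daughter_counts):
    """Run n_steps of surface Brownian dynamics with barrier rules in place.

    ``pos`` (n, 3), ``hint`` (n,) and ``unbleached`` (n,) are updated in
    place; per-sample unbleached counts in the mother (x < lobe_lo) and
    daughter (x > lobe_hi) lobes are written to the output arrays.
    """
    n = pos.shape[0]
    nv = X.shape[0]
    k_dom = intervals.shape[0]
    m_obs = obst.shape[0]
    ob_lo = 1e300
    ob_hi = -1e300
    if m_obs > 0:
        for j in range(m_obs):
            if obst[j, 0] < ob_lo:
                ob_lo = obst[j, 0]
            if obst[j, 0] > ob_hi:
                ob_hi = obst[j, 0]
        ob_lo -= contact_r + 6.0 * np.sqrt(2.0 * D_out * dt)
        ob_hi += contact_r + 6.0 * np.sqrt(2.0 * D_out * dt)
    cr2 = contact_r * contact_r
    spot_r2 = spot_rad * spot_rad
    sig_out = np.sqrt(2.0 * D_out * dt)
    sig_in = np.sqrt(2.0 * D_in * dt)
    sample_i = 0

    for step in range(1, n_steps + 1):
        for i in range(n):
            x = pos[i, 0]
            y = pos[i, 1]
            z = pos[i, 2]
            r = np.sqrt(y * y + z * z)
            idx = hint[i]
            s = idx
            if s > nv - 2:
                s = nv - 2
            dxs = X[s + 1] - X[s]
            drs = R[s + 1] - R[s]
            L = np.sqrt(dxs * dxs + drs * drs)
            tx = dxs / L
            tr = drs / L
            in_dom = False
            if k_dom > 0:
                in_dom = _member(x, intervals)
            sig = sig_in if in_dom else sig_out
            xi1 = rng.standard_normal() * sig
            xi2 = rng.standard_normal() * sig
            if r > 1e-12:
                cy = y / r
                cz = z / r
            else:
                cy = 1.0
                cz = 0.0
            nx = x + xi1 * tx
            ny = y + xi1 * tr * cy - xi2 * cz
            nz = z + xi1 * tr * cz + xi2 * cy
            nr = np.sqrt(ny * ny + nz * nz)
            w = int((abs(xi1) + abs(xi2)) / vertex_spacing) + 4
            px, pr, nidx = _project_local(X, R, nx, nr, idx, w)
            if nr > 1e-12:
                uy = ny / nr
                uz = nz / nr
            else:
                uy = cy
                uz = cz
            rejected = False
            if k_dom > 0:
                nd = _member(px, intervals)
                if nd != in_dom:
                    # Metropolis-Hastings factor for the step-size change keeps
                    # equilibrium partitioning at exactly P_in/P_out
                    sig_new = sig_in if nd else sig_out
                    s2 = sig * sig
                    s2n = sig_new * sig_new
                    acc = p_in_eff if nd else p_out
                    if s2 != s2n:
                        d2 = xi1 * xi1 + xi2 * xi2
                        ratio = (s2 / s2n) * np.exp(d2 / (2.0 * s2) - d2 / (2.0 * s2n))
                        if ratio < 1.0:
                            acc *= ratio
                    if rng.random() >= acc:
                        rejected = True
            if has_plane and not rejected:
                if (x - plane_pos) * (px - plane_pos) < 0.0:
                    if rng.random() >= plane_p:
                        rx = 2.0 * plane_pos - px
                        w2 = int(abs(rx - px) / vertex_spacing) + 8
                        qx, qr, qidx = _project_local(X, R, rx, pr, nidx, w2)
                        if (x - plane_pos) * (qx - plane_pos) > 0.0:
                            px = qx
                            pr = qr
                            nidx = qidx
                        else:
                            rejected = True
            nyf = pr * uy
            nzf = pr * uz
            if m_obs > 0 and not rejected:
                if (ob_lo <= px <= ob_hi) or (ob_lo <= x <= ob_hi):
                    ax = px - x
                    ay = nyf - y
                    az = nzf - z
                    a2 = ax * ax + ay * ay + az * az
                    for j in range(m_obs):
                        wx = obst[j, 0] - x
                        wy = obst[j, 1] - y
                        wz = obst[j, 2] - z
                        if a2 > 0.0:
                            t = (wx * ax + wy * ay + wz * az) / a2
                            if t < 0.0:
                                t = 0.0
                            elif t > 1.0:
                                t = 1.0
                        else:
                            t = 0.0
                        qx = wx - t * ax
                        qy = wy - t * ay
                        qz = wz - t * az
                        if qx * qx + qy * qy + qz * qz < cr2:
                            rejected = True
                            break
            if rejected:
                px = x
                nyf = y
                nzf = z
                nidx = idx
            pos[i, 0] = px
            pos[i, 1] = nyf
            pos[i, 2] = nzf
            hint[i] = nidx
            if p_bleach > 0.0 and unbleached[i]:
                ddx = px - spot_cx
                ddy = nyf - spot_cy
                azv = abs(nzf)
                ddz = azv - spot_half if azv > spot_half else 0.0
                if ddx * ddx + ddy * ddy + ddz * ddz <= spot_r2:
                    if rng.random() < p_bleach:
                        unbleached[i] = False
        if step % sample_every == 0:
            cm = 0
            cd = 0
            for i in range(n):
                if unbleached[i]:
                    if pos[i, 0] < lobe_lo:
                        cm += 1
                    elif pos[i, 0] > lobe_hi:
                        cd += 1
            mother_counts[sample_i] = cm
            daughter_counts[sample_i] = cd
            sample_i += 1
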