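"""Numba kernels for rod mechanics and time evolution.

Everything here operates on flat float64/int64 arrays so the whole
integration loop stays inside compiled code.  The Python-facing API in
:mod:`rodcolony.mechanics` and :mod:`rodcolony.dynamics` wraps these.

Conventions: positions/lengths in rod widths (2R = 1 by default), time
in generations, the rod "spine" is the centre-line segment of length
``l - 2R`` so that the spherocylinder of total length ``l`` is the set
of points within R of the spine.
"""

import math

import numpy as np
from numba import njit

DOMAIN_CHANNEL = 0
DOMAIN_OPEN = 1
DOMAIN_COLUMN = 2


# ---------------------------------------------------------------- RNG

@njit(cache=True, inline="always")
def _rng_next(state):
    """xorshift64* step; returns uniform float64 in [0, 1)."""
    s = state[0]
    s ^= s >> np.uint64(12)
    s ^= s << np.uint64(25)
    s ^= s >> np.uint64(27)
    state[0] = s
    z = s * np.uint64(2685821657736338717)
    return float(z >> np.uint64(11)) / 9007199254740992.0


# ------------------------------------------------- segment geometry

@njit(cache=True, inline="always")
def _clamp01(t):
    if t < 0.0:
        return 0.0
    if t > 1.0:
        return 1.0
    return t


@njit(cache=True)
def seg_closest_points(p1x, p1y, q1x, q1y, p2x, p2y, q2x, q2y):
    """Closest points between segments [p1,q1] and [p2,q2].

    Returns (ax, ay, bx, by): the contact point on each segment.  For
    exactly parallel segments whose projections overlap, the contact is
    placed at the midpoint of the overlap interval (symmetric
    tie-break); degenerate zero-length segments are treated as points.
    """
    d1x = q1x - p1x
    d1y = q1y - p1y
    d2x = q2x - p2x
    d2y = q2y - p2y
    rx = p1x - p2x
    ry = p1y - p2y
    a = d1x * d1x + d1y * d1y
    e = d2x * d2x + d2y * d2y
    f = d2x * rx + d2y * ry
    EPS = 1e-14
    if a <= EPS and e <= EPS:
        return p1x, p1y, p2x, p2y
    if a <= EPS:
        t = _clamp01(f / e)
        return p1x, p1y, p2x + t * d2x, p2y + t * d2y
    c = d1x * rx + d1y * ry
    if e <= EPS:
        s = _clamp01(-c / a)
        return p1x + s * d1x, p1y + s * d1y, p2x, p2y
    b = d1x * d2x + d1y * d2y
    denom = a * e - b * b
    if denom > 1e-12 * a * e:
        s = _clamp01((b * f - c * e) / denom)
        t = (b * s + f) / e
        if t < 0.0:
            t = 0.0
            s = _clamp01(-c / a)
        elif t > 1.0:
            t = 1.0
            s = _clamp01((b - c) / a)
        return (p1x + s * d1x, p1y + s * d1y,
                p2x + t * d2x, p2y + t * d2y)
    # parallel segments: project segment 2 onto the axis of segment 1
    L1 = math.sqrt(a)
    ux = d1x / L1
    uy = d1y / L1
    t0 = (p2x - p1x) * ux + (p2y - p1y) * uy
    t1 = (q2x - p1x) * ux + (q2y - p1y) * uy
    lo2 = min(t0, t1)
    hi2 = max(t0, t1)
    lo = max(0.0, lo2)
    hi = min(L1, hi2)
    if lo <= hi:
        sm = 0.5 * (lo + hi)
        ax = p1x + sm * ux
        ay = p1y + sm * uy
        tt = _clamp01(((ax - p2x) * d2x + (ay - p2y) * d2y) / e)
        return ax, ay, p2x + tt * d2x, p2y + tt * d2y
    if hi2 < 0.0:
        # segment 2 lies entirely before the start of segment 1
        ax = p1x
        ay = p1y
    else:
        ax = q1x
        ay = q1y
    tt = _clamp01(((ax - p2x) * d2x + (ay - p2y) * d2y) / e)
    return ax, ay, p2x + tt * d2x, p2y + tt * d2y


# --------------------------------------------------------- mobility

@njit(cache=True, inline="always")
def tirado_mobilities(l, R, zeta0):
    """Tirado & Garcia de la Torre short-cylinder mobilities.

    Aspect ratio p = l / 2R; returns (mu_par, mu_perp, mu_rot) with the
    end-corrected logarithmic series, scaled by 1/zeta0.
    """
    p = l / (2.0 * R)
    lnp = math.log(p)
    ip = 1.0 / p
    nu_par = -0.207 + 0.980 * ip - 0.133 * ip * ip
    nu_perp = 0.839 + 0.185 * ip + 0.233 * ip * ip
    nu_rot = -0.662 + 0.917 * ip - 0.050 * ip * ip
    mu_par = (lnp + nu_par) / (2.0 * math.pi * zeta0 * l)
    mu_perp = (lnp + nu_perp) / (4.0 * math.pi * zeta0 * l)
    mu_rot = 3.0 * (lnp + nu_rot) / (math.pi * zeta0 * l * l * l)
    return mu_par, mu_perp, mu_rot


# ------------------------------------------------------ contact pass

@njit(cache=True, fastmath=True)
def _forces(x, y, phi, l, n, R, ypref, domain_kind, W, H,
            cell_size, ncx, ncy, head, nxt,
            ux_a, uy_a, fx, fy, tq, load_p, load_m):
    """Resolve all pair and wall contacts; accumulate forces, torques
    about each rod centre, and compressive axial tip loads per half-rod.

    Returns the maximum contact overlap seen (diagnostic).
    """
    two_R = 2.0 * R
    for i in range(n):
        fx[i] = 0.0
        fy[i] = 0.0
        tq[i] = 0.0
        load_p[i] = 0.0
        load_m[i] = 0.0
        ux_a[i] = math.cos(phi[i])
        uy_a[i] = math.sin(phi[i])
    # bin rods into the uniform grid
    for c in range(ncx * ncy):
        head[c] = -1
    x0 = -0.5 * W
    y0 = -0.5 * H
    for i in range(n):
        cx = int((x[i] - x0) / cell_size)
        cy = int((y[i] - y0) / cell_size)
        if cx < 0:
            cx = 0
        elif cx >= ncx:
            cx = ncx - 1
        if cy < 0:
            cy = 0
        elif cy >= ncy:
            cy = ncy - 1
        c = cy * ncx + cx
        nxt[i] = head[c]
        head[c] = i
    max_overlap = 0.0
    for i in range(n):
        ci = int((x[i] - x0) / cell_size)
        cj = int((y[i] - y0) / cell_size)
        if ci < 0:
            ci = 0
        elif ci >= ncx:
            ci = ncx - 1
        if cj < 0:
            cj = 0
        elif cj >= ncy:
            cj = ncy - 1
        si = 0.5 * l[i] - R
        uxi = ux_a[i]
        uyi = uy_a[i]
        p1x = x[i] - si * uxi
        p1y = y[i] - si * uyi
        q1x = x[i] + si * uxi
        q1y = y[i] + si * uyi
        # half-neighbourhood sweep: each unordered pair visited once
        # (same cell with j > i, plus 12 positive-offset cells)
        for koff in range(13):
            if koff == 0:
                dcx = 0
                dcy = 0
            elif koff == 1:
                dcx = 1
                dcy = 0
            elif koff == 2:
                dcx = 2
                dcy = 0
            else:
                dcy = 1 + (koff - 3) // 5
                dcx = (koff - 3) % 5 - 2
            ccx = ci + dcx
            ccy = cj + dcy
            if ccx < 0 or ccx >= ncx or ccy < 0 or ccy >= ncy:
                continue
            same = koff == 0
            j = head[ccy * ncx + ccx]
            while j != -1:
                if same and j <= i:
                    j = nxt[j]
                    continue
                dxc = x[i] - x[j]
                dyc = y[i] - y[j]
                reach = si + 0.5 * l[j] - R + two_R
                if dxc * dxc + dyc * dyc > reach * reach:
                    j = nxt[j]
                    continue
                sj = 0.5 * l[j] - R
                uxj = ux_a[j]
                uyj = uy_a[j]
                ax, ay, bx, by = seg_closest_points(
                    p1x, p1y, q1x, q1y,
                    x[j] - sj * uxj, y[j] - sj * uyj,
                    x[j] + sj * uxj, y[j] + sj * uyj)
                ddx = ax - bx
                ddy = ay - by
                dist = math.sqrt(ddx * ddx + ddy * ddy)
                if dist < two_R:
                    ov = two_R - dist
                    if ov > max_overlap:
                        max_overlap = ov
                    if dist < 1e-12:
                        # fully coincident centre lines: push apart
                        # along the centre-to-centre direction
                        rc = math.sqrt(dxc * dxc + dyc * dyc)
                        if rc < 1e-12:
                            j = nxt[j]
                            continue
                        ddx = dxc / rc
                        ddy = dyc / rc
                        dist = 1.0
                    fmag = ypref * ov * math.sqrt(ov)
                    fxx = fmag * ddx / dist
                    fyy = fmag * ddy / dist
                    fx[i] += fxx
                    fy[i] += fyy
                    fx[j] -= fxx
                    fy[j] -= fyy
                    # torques about rod centres
                    tq[i] += (ax - x[i]) * fyy - (ay - y[i]) * fxx
                    tq[j] -= (bx - x[j]) * fyy - (by - y[j]) * fxx
                    # compressive axial loads on each half
                    s_i = (ax - x[i]) * uxi + (ay - y[i]) * uyi
                    f_ax = fxx * uxi + fyy * uyi
                    if s_i > 0.0 and f_ax < 0.0:
                        load_p[i] -= f_ax
                    elif s_i < 0.0 and f_ax > 0.0:
                        load_m[i] += f_ax
                    s_j = (bx - x[j]) * uxj + (by - y[j]) * uyj
                    f_axj = -(fxx * uxj + fyy * uyj)
                    if s_j > 0.0 and f_axj < 0.0:
                        load_p[j] -= f_axj
                    elif s_j < 0.0 and f_axj > 0.0:
                        load_m[j] += f_axj
                j = nxt[j]
        # wall forces (channel confinement in x)
        if domain_kind == DOMAIN_CHANNEL:
            for side in range(2):
                wall = 0.5 * W if side == 0 else -0.5 * W
                if side == 0:
                    ex = q1x if q1x > p1x else p1x
                    dlin = wall - ex
                else:
                    ex = q1x if q1x < p1x else p1x
                    dlin = ex - wall
                if dlin < two_R:
                    if abs(q1x - p1x) < 1e-9:
                        cxp = x[i]
                        cyp = y[i]
                    elif (side == 0) == (q1x > p1x):
                        cxp = q1x
                        cyp = q1y
                    else:
                        cxp = p1x
                        cyp = p1y
                    ov = two_R - dlin
                    if ov > max_overlap:
                        max_overlap = ov
                    fmag = ypref * ov * math.sqrt(ov)
                    fxx = -fmag if side == 0 else fmag
                    fx[i] += fxx
                    tq[i] += (cxp - x[i]) * 0.0 - (cyp - y[i]) * fxx
                    s_i = (cxp - x[i]) * uxi + (cyp - y[i]) * uyi
                    f_ax = fxx * uxi
                    if s_i > 0.0 and f_ax < 0.0:
                        load_p[i] -= f_ax
                    elif s_i < 0.0 and f_ax > 0.0:
                        load_m[i] += f_ax
    return max_overlap


@njit(cache=True)
def resolve_contacts(x, y, phi, l, n, R, ypref,
                     out_i, out_j, out_dx, out_dy, out_fx, out_fy,
                     cell_size, ncx, ncy, head, nxt, W, H):
    """List all active pair contacts.

    Writes (k, l, d, F_kl) per unordered pair into the out arrays where
    ``d`` is the shortest connection between centre lines and ``F_kl``
    the force on rod k; returns the number of contacts (or -1 if the
    output capacity was exceeded).
    """
    two_R = 2.0 * R
    for c in range(ncx * ncy):
        head[c] = -1
    x0 = -0.5 * W
    y0 = -0.5 * H
    for i in range(n):
        cx = min(max(int((x[i] - x0) / cell_size), 0), ncx - 1)
        cy = min(max(int((y[i] - y0) / cell_size), 0), ncy - 1)
        c = cy * ncx + cx
        nxt[i] = head[c]
        head[c] = i
    m = 0
    cap = out_i.shape[0]
    for i in range(n):
        ci = min(max(int((x[i] - x0) / cell_size), 0), ncx - 1)
        cj = min(max(int((y[i] - y0) / cell_size), 0), ncy - 1)
        si = 0.5 * l[i] - R
        uxi = math.cos(phi[i])
        uyi = math.sin(phi[i])
        p1x = x[i] - si * uxi
        p1y = y[i] - si * uyi
        q1x = x[i] + si * uxi
        q1y = y[i] + si * uyi
        for dcy in range(-2, 3):
            ccy = cj + dcy
            if ccy < 0 or ccy >= ncy:
                continue
            for dcx in range(-2, 3):
                ccx = ci + dcx
                if ccx < 0 or ccx >= ncx:
                    continue
                j = head[ccy * ncx + ccx]
                while j != -1:
                    if j <= i:
                        j = nxt[j]
                        continue
                    dxc = x[i] - x[j]
                    dyc = y[i] - y[j]
                    reach = si + 0.5 * l[j] - R + two_R
                    if dxc * dxc + dyc * dyc > reach * reach:
                        j = nxt[j]
                        continue
                    sj = 0.5 * l[j] - R
                    uxj = math.cos(phi[j])
                    uyj = math.sin(phi[j])
                    ax, ay, bx, by = seg_closest_points(
                        p1x, p1y, q1x, q1y,
                        x[j] - sj * uxj, y[j] - sj * uyj,
                        x[j] + sj * uxj, y[j] + sj * uyj)
                    ddx = ax - bx
                    ddy = ay - by
                    dist = math.sqrt(ddx * ddx + ddy * ddy)
                    if dist < two_R and dist > 1e-12:
                        if m >= cap:
                            return -1
                        ov = two_R - dist
                        fmag = ypref * ov * math.sqrt(ov)
                        out_i[m] = i
                        out_j[m] = j
                        out_dx[m] = ddx
                        out_dy[m] = ddy
                        out_fx[m] = fmag * ddx / dist
                        out_fy[m] = fmag * ddy / dist
                        m += 1
                    j = nxt[j]
    return m


# ------------------------------------------------------ time stepping

@njit(cache=True, fastmath=True)
def advance(x, y, phi, l_rest, l, gamma, ids, n_arr,
            t_arr, t_target,
            R, lmax, ypref, kc, dt, zeta0,
            domain_kind, W, H, glo, ghi,
            rng_state, next_id,
            cell_size, ncx, ncy, head, nxt,
            ux_a, uy_a, fx, fy, tq, load_p, load_m,
            diag):
    """Advance the population until time t_target.

    Mutates the state arrays in place.  ``n_arr`` holds the live rod
    count, ``t_arr`` the current time, ``next_id`` the next fresh id,
    ``rng_state`` the xorshift64* state.  ``diag`` accumulates
    [n_halvings, max_overlap].  Returns 0 on success, 1 when the array
    capacity would be exceeded (caller grows arrays and re-calls).
    """
    n = n_arr[0]
    t = t_arr[0]
    cap = x.shape[0]
    two_R = 2.0 * R
    disp_cap = 0.1 * R
    half_growth = 0.5 * lmax
    while t < t_target - 1e-15:
        dt_step = dt
        if t + dt_step > t_target:
            dt_step = t_target - t
        mo = _forces(x, y, phi, l, n, R, ypref, domain_kind, W, H,
                     cell_size, ncx, ncy, head, nxt,
                     ux_a, uy_a, fx, fy, tq, load_p, load_m)
        if mo > diag[1]:
            diag[1] = mo
        # quasi-static axial compression against the internal spring
        for i in range(n):
            P = 0.5 * (load_p[i] + load_m[i])
            li = l_rest[i] - (P / kc) ** (2.0 / 3.0)
            if li < two_R:
                li = two_R
            l[i] = li
        # overdamped velocities and the step-size guard
        maxdisp = 0.0
        for i in range(n):
            mu_par, mu_perp, mu_rot = tirado_mobilities(l[i], R, zeta0)
            ux = ux_a[i]
            uy = uy_a[i]
            fpar = fx[i] * ux + fy[i] * uy
            fperp = -fx[i] * uy + fy[i] * ux
            vx = mu_par * fpar * ux - mu_perp * fperp * uy
            vy = mu_par * fpar * uy + mu_perp * fperp * ux
            om = mu_rot * tq[i]
            if domain_kind == DOMAIN_COLUMN:
                vx = 0.0
                om = 0.0
            # reuse force arrays as velocity scratch
            fx[i] = vx
            fy[i] = vy
            tq[i] = om
            disp = (math.sqrt(vx * vx + vy * vy)
                    + abs(om) * 0.5 * l[i]) * dt_step
            if disp > maxdisp:
                maxdisp = disp
        while maxdisp > disp_cap and dt_step > 1e-12:
            dt_step *= 0.5
            maxdisp *= 0.5
            diag[0] += 1
        for i in range(n):
            x[i] += dt_step * fx[i]
            y[i] += dt_step * fy[i]
            phi[i] += dt_step * tq[i]
            dl = dt_step * gamma[i] * half_growth
            l_rest[i] += dl
            li = l[i] + dl
            if li > l_rest[i]:
                li = l_rest[i]
            l[i] = li
        t += dt_step
        # divisions
        n_before = n
        for i in range(n_before):
            if l_rest[i] >= lmax:
                if n >= cap:
                    n_arr[0] = n
                    t_arr[0] = t
                    return 1
                deficit = l_rest[i] - l[i]
                ux = math.cos(phi[i])
                uy = math.sin(phi[i])
                off = 0.25 * l[i]
                cx = x[i]
                cy = y[i]
                child_l = 0.5 * lmax - 0.5 * deficit
                if child_l < two_R:
                    child_l = two_R
                # daughter A replaces the mother slot
                x[i] = cx - off * ux
                y[i] = cy - off * uy
                l_rest[i] = 0.5 * lmax
                l[i] = child_l
                gamma[i] = glo + (ghi - glo) * _rng_next(rng_state)
                ids[i] = next_id[0]
                next_id[0] += 1
                # daughter B appended
                x[n] = cx + off * ux
                y[n] = cy + off * uy
                phi[n] = phi[i]
                l_rest[n] = 0.5 * lmax
                l[n] = child_l
                gamma[n] = glo + (ghi - glo) * _rng_next(rng_state)
                ids[n] = next_id[0]
                next_id[0] += 1
                n += 1
        # outlet removal (centre-point criterion)
        i = 0
        while i < n:
            out = False
            if abs(y[i]) > 0.5 * H:
                out = True
            if domain_kind == DOMAIN_OPEN and abs(x[i]) > 0.5 * W:
                out = True
            if out:
                n -= 1
                x[i] = x[n]
                y[i] = y[n]
                phi[i] = phi[n]
                l_rest[i] = l_rest[n]
                l[i] = l[n]
                gamma[i] = gamma[n]
                ids[i] = ids[n]
            else:
                i += 1
    n_arr[0] = n
    t_arr[0] = t
    return 0
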