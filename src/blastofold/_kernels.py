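"""Numba-compiled inner loops: energy/forces, boundary projection, integration.

All kernels operate on plain float64 arrays; the object-level API lives in
:mod:`blastofold.dynamics`.  The discrete energy is

    W*_T = 1/2 K_s sum_{i=2}^{N-3} (dr_i/dr_o - 1)^2 dr_o
         + 1/2 K_b sum_{i=2}^{N-3} (kappa_i - kappa_{o,i})^2 dr_o

with 0-based particle indices, ``dr_i`` the spring between particles ``i``
and ``i+1`` and ``kappa_i`` the discrete signed curvature at particle ``i``
(turning angle over mean incident segment length).  The index range covers
exactly the particles/springs with full neighbour support away from the two
fixed particles at each end, and is re-evaluated from the current particle
count after mitotic insertion.

Sign convention: curvature that follows the convex elliptical boundary is
positive; an invagination toward the embryo interior is negative.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by run_segment
STATUS_OK = 0
STATUS_NONFINITE = 1


@njit(cache=True)
def signed_curvature(ax, ay, bx, by):
    """Discrete curvature from incident segments a (incoming) and b (outgoing).

    kappa = 2 sin(theta/2) / mean(|a|, |b|), theta the signed turning angle,
    with the sign flipped so traversal along the convex boundary (anterior
    pole toward posterior, clockwise) is positive.  Equals exactly 1/R for
    points equally spaced on a circle of radius R.
    """
    l1 = np.sqrt(ax * ax + ay * ay)
    l2 = np.sqrt(bx * bx + by * by)
    c = -(ax * by - ay * bx)  # sign flip: boundary-following positive
    d = ax * bx + ay * by
    q = l1 * l2
    s2 = 2.0 * q * (q + d)
    if s2 < 1e-300:
        s2 = 1e-300
    s = np.sqrt(s2)
    return 4.0 * c / ((l1 + l2) * s)


@njit(cache=True, fastmath=True)
def energy_and_forces(pos, kappa0, dr0, Ks, Kb, grad):
    """Fill ``grad`` with dW*/dr_i and return (W_s, W_b).

    ``grad`` is the raw energy gradient (force = -grad); entries for fixed
    particles are zeroed by the caller's free mask during integration.
    """
    N = pos.shape[0]
    for i in range(N):
        grad[i, 0] = 0.0
        grad[i, 1] = 0.0
    Ws = 0.0
    Wb = 0.0
    # stretching: springs i = 2 .. N-3 (spring i connects particles i, i+1)
    for i in range(2, N - 2):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dr = np.sqrt(dx * dx + dy * dy)
        strain = dr / dr0 - 1.0
        Ws += 0.5 * Ks * strain * strain * dr0
        if dr > 0.0:
            f = Ks * strain / dr
            grad[i + 1, 0] += f * dx
            grad[i + 1, 1] += f * dy
            grad[i, 0] -= f * dx
            grad[i, 1] -= f * dy
    # bending: particles i = 2 .. N-3
    for i in range(2, N - 2):
        ax = pos[i, 0] - pos[i - 1, 0]
        ay = pos[i, 1] - pos[i - 1, 1]
        bx = pos[i + 1, 0] - pos[i, 0]
        by = pos[i + 1, 1] - pos[i, 1]
        l1 = np.sqrt(ax * ax + ay * ay)
        l2 = np.sqrt(bx * bx + by * by)
        c = -(ax * by - ay * bx)
        d = ax * bx + ay * by
        P = l1 + l2
        Q = l1 * l2
        s2 = 2.0 * Q * (Q + d)
        if s2 < 1e-300:
            s2 = 1e-300
        s = np.sqrt(s2)
        inv_s2 = 1.0 / s2
        inv_s = s * inv_s2          # 1/s = s/s^2
        inv_P = 1.0 / P
        inv_Q = 1.0 / Q
        kappa = 4.0 * c * inv_P * inv_s
        dk = kappa - kappa0[i]
        Wb += 0.5 * Kb * dk * dk * dr0
        w = Kb * dk * dr0  # dW/dkappa
        # partials of kappa w.r.t. c, d, l1, l2
        r1 = inv_P * inv_s
        r3 = inv_P * inv_s2 * inv_s
        rPP = inv_P * inv_P * inv_s
        dk_dc = 4.0 * r1
        dk_dd = -4.0 * c * Q * r3
        dk_dl1 = -4.0 * c * (rPP + (2.0 * Q + d) * l2 * r3)
        dk_dl2 = -4.0 * c * (rPP + (2.0 * Q + d) * l1 * r3)
        inv_l1 = l2 * inv_Q
        inv_l2 = l1 * inv_Q
        # chain to segment vectors; note c = -(a x b)
        gax = w * (dk_dc * (-by) + dk_dd * bx + dk_dl1 * ax * inv_l1)
        gay = w * (dk_dc * (bx) + dk_dd * by + dk_dl1 * ay * inv_l1)
        gbx = w * (dk_dc * (ay) + dk_dd * ax + dk_dl2 * bx * inv_l2)
        gby = w * (dk_dc * (-ax) + dk_dd * ay + dk_dl2 * by * inv_l2)
        # a = r_i - r_{i-1}, b = r_{i+1} - r_i
        grad[i - 1, 0] -= gax
        grad[i - 1, 1] -= gay
        grad[i, 0] += gax - gbx
        grad[i, 1] += gay - gby
        grad[i + 1, 0] += gbx
        grad[i + 1, 1] += gby
    return Ws, Wb


@njit(cache=True)
def project_point(px, py, qx, qy, L, bL):
    """Confine a proposed move to the rigid elliptical boundary.

    ``(px, py)`` is the previous (valid) position, ``(qx, qy)`` the
    proposal.  If the proposal is inside or on the boundary it is returned
    unchanged; otherwise the intersection of the segment previous->proposed
    with the ellipse is returned (root of a quadratic in the segment
    parameter, taken in [0, 1]).
    """
    X1 = qx / L
    Y1 = qy / bL
    if X1 * X1 + Y1 * Y1 <= 1.0:
        return qx, qy
    X0 = px / L
    Y0 = py / bL
    DX = X1 - X0
    DY = Y1 - Y0
    A = DX * DX + DY * DY
    if A == 0.0:
        return px, py
    B = 2.0 * (X0 * DX + Y0 * DY)
    C = X0 * X0 + Y0 * Y0 - 1.0
    if C > 0.0:
        C = 0.0  # previous numerically on the boundary
    disc = B * B - 4.0 * A * C
    if disc < 0.0:
        disc = 0.0
    t = (-B + np.sqrt(disc)) / (2.0 * A)
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return px + t * (qx - px), py + t * (qy - py)


@njit(cache=True)
def ellipse_boundary_distance(x, y, L, bL):
    """Euclidean distance from an interior point to the elliptical boundary.

    Solves the closest-point condition on the parametric ellipse by a
    bracketed Newton/bisection hybrid in the first quadrant (the problem is
    symmetric in both axes).  Accurate to ~1e-12 * L.
    """
    px = abs(x)
    py = abs(y)
    if px + py < 1e-14 * L:
        return bL  # center: nearest boundary point is the co-vertex
    a = L
    b = bL
    lo = 0.0
    hi = 0.5 * np.pi
    # f(u) = (a^2 - b^2) cos u sin u - px a sin u + py b cos u
    # f(0) = py b >= 0, f(pi/2) = -px a <= 0: root bracketed
    u = np.arctan2(a * py, b * px)
    for _ in range(80):
        cu = np.cos(u)
        su = np.sin(u)
        f = (a * a - b * b) * cu * su - px * a * su + py * b * cu
        if f > 0.0:
            lo = u
        else:
            hi = u
        fp = (a * a - b * b) * (cu * cu - su * su) - px * a * cu - py * b * su
        if fp != 0.0:
            un = u - f / fp
        else:
            un = 0.5 * (lo + hi)
        if un <= lo or un >= hi:
            un = 0.5 * (lo + hi)
        if abs(un - u) < 1e-15:
            u = un
            break
        u = un
    dx = px - a * np.cos(u)
    dy = py - b * np.sin(u)
    return np.sqrt(dx * dx + dy * dy)


@njit(cache=True)
def boundary_distances(pos, L, bL, out):
    for i in range(pos.shape[0]):
        out[i] = ellipse_boundary_distance(pos[i, 0], pos[i, 1], L, bL)


@njit(cache=True, fastmath=True)
def run_chunk(pos, free_idx, kappa0, dr0, Ks, Kb, L, beta, pref, sigma,
              noise, step0, record_every, rec_pos, rec_energy, rec_k):
    """Integrate ``noise.shape[0]`` explicit-Euler steps of the dynamics.

    ``noise`` holds pre-drawn standard-normal increments, one row per step
    with ``2 * len(free_idx)`` entries (x, y interleaved per free particle).
    Each free particle moves by ``-pref * grad`` plus ``sigma`` times its
    noise entries; proposals leaving the ellipse are projected back onto the
    boundary along the displacement segment.

    Global step numbering starts at ``step0``; whenever a completed step is
    a multiple of ``record_every`` the configuration and its (W_s, W_b) are
    written to ``rec_pos[rec_k]`` / ``rec_energy[rec_k]``.

    Returns (status, iteration, rec_k): STATUS_NONFINITE flags the first
    recorded iteration at which a coordinate stopped being finite.
    """
    N = pos.shape[0]
    bL = beta * L
    inv_L = 1.0 / L
    inv_bL = 1.0 / bL
    grad = np.empty((N, 2))
    nf = free_idx.shape[0]
    n_sub = noise.shape[0]
    for s in range(n_sub):
        t = step0 + s + 1
        energy_and_forces(pos, kappa0, dr0, Ks, Kb, grad)
        for j in range(nf):
            i = free_idx[j]
            qx = pos[i, 0] - pref * grad[i, 0] + sigma * noise[s, 2 * j]
            qy = pos[i, 1] - pref * grad[i, 1] + sigma * noise[s, 2 * j + 1]
            X1 = qx * inv_L
            Y1 = qy * inv_bL
            if X1 * X1 + Y1 * Y1 > 1.0:
                # inline segment-ellipse intersection (see project_point)
                X0 = pos[i, 0] * inv_L
                Y0 = pos[i, 1] * inv_bL
                DX = X1 - X0
                DY = Y1 - Y0
                A = DX * DX + DY * DY
                if A > 0.0:
                    B = 2.0 * (X0 * DX + Y0 * DY)
                    C = X0 * X0 + Y0 * Y0 - 1.0
                    if C > 0.0:
                        C = 0.0
                    disc = B * B - 4.0 * A * C
                    if disc < 0.0:
                        disc = 0.0
                    tt = (-B + np.sqrt(disc)) * 0.5 / A
                    if tt < 0.0:
                        tt = 0.0
                    elif tt > 1.0:
                        tt = 1.0
                    qx = pos[i, 0] + tt * (qx - pos[i, 0])
                    qy = pos[i, 1] + tt * (qy - pos[i, 1])
                else:
                    qx = pos[i, 0]
                    qy = pos[i, 1]
            pos[i, 0] = qx
            pos[i, 1] = qy
        if t % record_every == 0:
            total = 0.0
            for i in range(N):
                rec_pos[rec_k, i, 0] = pos[i, 0]
                rec_pos[rec_k, i, 1] = pos[i, 1]
                total += pos[i, 0] + pos[i, 1]
            if not np.isfinite(total):
                return STATUS_NONFINITE, t, rec_k
            Ws, Wb = energy_and_forces(pos, kappa0, dr0, Ks, Kb, grad)
            rec_energy[rec_k, 0] = Ws
            rec_energy[rec_k, 1] = Wb
            rec_k += 1
    return STATUS_OK, step0 + n_sub, rec_k


@njit(cache=True)
def max_boundary_excursion(frames, L, bL):
    """Maximum particle-to-boundary distance over a (T, N, 2) frame stack."""
    best = 0.0
    for f in range(frames.shape[0]):
        for i in range(frames.shape[1]):
            d = ellipse_boundary_distance(frames[f, i, 0], frames[f, i, 1], L, bL)
            if d > best:
                best = d
    return best
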