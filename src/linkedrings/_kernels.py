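"""Numba-compiled computational kernels.

Everything here operates on plain float64/int64 arrays so the jitted code
stays free of Python objects.  Positions handed to these kernels are always
*unwrapped* coordinates; periodicity (along x only) is applied internally
through the minimum-image convention when computing pair distances.

Status codes returned by the force/integration kernels:
    0  success
    1  FENE bond overstretched (r >= r0): topology-violating step
    2  bead radially outside the channel wall
    3  non-finite coordinate encountered
"""

from __future__ import annotations

import numpy as np
from numba import njit

TWO_16 = 2.0 ** (1.0 / 6.0)


# ---------------------------------------------------------------------------
# Force evaluation
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def build_pairs(pos, period_x, cutoff, out_pairs):
    """All bead pairs within ``cutoff`` (min image along x); returns count."""
    n = pos.shape[0]
    half_px = 0.5 * period_x
    c2 = cutoff * cutoff
    count = 0
    cap = out_pairs.shape[0]
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            if period_x > 0.0:
                while dx > half_px:
                    dx -= period_x
                while dx < -half_px:
                    dx += period_x
            if dx > cutoff or dx < -cutoff:
                continue
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < c2:
                if count < cap:
                    out_pairs[count, 0] = i
                    out_pairs[count, 1] = j
                count += 1
    return count


@njit(cache=True, fastmath=True)
def compute_forces_nl(pos, pairs, n_pairs, bonds, angles, eps, sig, fene_k,
                      fene_r0, kappa, diameter, period_x, ext_f, f_out):
    """Accumulate all conservative forces into ``f_out`` using a
    precomputed pair list; return status."""
    n = pos.shape[0]
    f_out[:] = 0.0
    rc2 = (TWO_16 * sig) ** 2
    sig2 = sig * sig
    half_px = 0.5 * period_x

    # WCA over the pair list (min image along x when periodic)
    for k in range(n_pairs):
        i = pairs[k, 0]
        j = pairs[k, 1]
        dx = pos[i, 0] - pos[j, 0]
        if period_x > 0.0:
            while dx > half_px:
                dx -= period_x
            while dx < -half_px:
                dx += period_x
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 < rc2 and r2 > 0.0:
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                # f/r = 24 eps (2 s12 - s6) / r^2
                fr = 24.0 * eps * (2.0 * s6 * s6 - s6) / r2
                f_out[i, 0] += fr * dx
                f_out[i, 1] += fr * dy
                f_out[i, 2] += fr * dz
                f_out[j, 0] -= fr * dx
                f_out[j, 1] -= fr * dy
                f_out[j, 2] -= fr * dz

    # FENE bonds (unwrapped distance; bonded beads are always near)
    r02 = fene_r0 * fene_r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return 1
        # f/r = -k / (1 - r^2/r0^2)
        fr = -fene_k / (1.0 - r2 / r02)
        f_out[i, 0] += fr * dx
        f_out[i, 1] += fr * dy
        f_out[i, 2] += fr * dz
        f_out[j, 0] -= fr * dx
        f_out[j, 1] -= fr * dy
        f_out[j, 2] -= fr * dz

    # Bending: U = kappa * (1 - cos theta) over consecutive bond pairs
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        # bond vectors b1 = rj - ri, b2 = rk - rj
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        if n1 == 0.0 or n2 == 0.0:
            return 3
        inv12 = 1.0 / (n1 * n2)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) * inv12
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        # dU/dcos = -kappa ; F = kappa * d(cos)/dr
        # d cos / d b1 = b2/(|b1||b2|) - cos * b1/|b1|^2, similarly for b2
        g1x = kappa * (b2x * inv12 - c * b1x / (n1 * n1))
        g1y = kappa * (b2y * inv12 - c * b1y / (n1 * n1))
        g1z = kappa * (b2z * inv12 - c * b1z / (n1 * n1))
        g2x = kappa * (b1x * inv12 - c * b2x / (n2 * n2))
        g2y = kappa * (b1y * inv12 - c * b2y / (n2 * n2))
        g2z = kappa * (b1z * inv12 - c * b2z / (n2 * n2))
        # dU/dri = -g1 ; dU/drj = g1 - g2 ; dU/drk = g2   (force = -dU/dr)
        f_out[i, 0] -= g1x
        f_out[i, 1] -= g1y
        f_out[i, 2] -= g1z
        f_out[j, 0] += g1x - g2x
        f_out[j, 1] += g1y - g2y
        f_out[j, 2] += g1z - g2z
        f_out[k, 0] += g2x
        f_out[k, 1] += g2y
        f_out[k, 2] += g2z

    # Channel wall: WCA on the radial gap D/2 - rho
    if np.isfinite(diameter):
        radius = 0.5 * diameter
        rc = TWO_16 * sig
        for i in range(n):
            rho = np.sqrt(pos[i, 1] * pos[i, 1] + pos[i, 2] * pos[i, 2])
            gap = radius - rho
            if gap <= 0.0:
                return 2
            if gap < rc and rho > 0.0:
                s2 = sig2 / (gap * gap)
                s6 = s2 * s2 * s2
                fw = 24.0 * eps * (2.0 * s6 * s6 - s6) / gap  # magnitude, inward
                f_out[i, 1] -= fw * pos[i, 1] / rho
                f_out[i, 2] -= fw * pos[i, 2] / rho

    # External (pulling) forces
    for i in range(n):
        f_out[i, 0] += ext_f[i, 0]
        f_out[i, 1] += ext_f[i, 1]
        f_out[i, 2] += ext_f[i, 2]

    return 0


@njit(cache=True, fastmath=True)
def compute_forces(pos, bonds, angles, eps, sig, fene_k, fene_r0,
                   kappa, diameter, period_x, ext_f, f_out):
    """One-shot force evaluation (builds its own exact pair list)."""
    n = pos.shape[0]
    cap = max(64, 40 * n)
    pairs = np.empty((cap, 2), dtype=np.int64)
    n_pairs = build_pairs(pos, period_x, TWO_16 * sig, pairs)
    if n_pairs > cap:
        return 3
    return compute_forces_nl(pos, pairs, n_pairs, bonds, angles, eps, sig,
                             fene_k, fene_r0, kappa, diameter, period_x,
                             ext_f, f_out)


@njit(cache=True, fastmath=True)
def total_potential_energy(pos, bonds, angles, eps, sig, fene_k, fene_r0,
                           kappa, diameter, period_x):
    """Total potential energy of a conformation (matches compute_forces)."""
    n = pos.shape[0]
    rc2 = (TWO_16 * sig) ** 2
    sig2 = sig * sig
    half_px = 0.5 * period_x
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = pos[i, 0] - pos[j, 0]
            if period_x > 0.0:
                while dx > half_px:
                    dx -= period_x
                while dx < -half_px:
                    dx += period_x
            dy = pos[i, 1] - pos[j, 1]
            dz = pos[i, 2] - pos[j, 2]
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < rc2 and r2 > 0.0:
                s2 = sig2 / r2
                s6 = s2 * s2 * s2
                e += 4.0 * eps * (s6 * s6 - s6) + eps
    r02 = fene_r0 * fene_r0
    for b in range(bonds.shape[0]):
        i = bonds[b, 0]
        j = bonds[b, 1]
        dx = pos[i, 0] - pos[j, 0]
        dy = pos[i, 1] - pos[j, 1]
        dz = pos[i, 2] - pos[j, 2]
        r2 = dx * dx + dy * dy + dz * dz
        if r2 >= r02:
            return np.inf
        e += -0.5 * fene_k * r02 * np.log(1.0 - r2 / r02)
    for a in range(angles.shape[0]):
        i = angles[a, 0]
        j = angles[a, 1]
        k = angles[a, 2]
        b1x = pos[j, 0] - pos[i, 0]
        b1y = pos[j, 1] - pos[i, 1]
        b1z = pos[j, 2] - pos[i, 2]
        b2x = pos[k, 0] - pos[j, 0]
        b2y = pos[k, 1] - pos[j, 1]
        b2z = pos[k, 2] - pos[j, 2]
        n1 = np.sqrt(b1x * b1x + b1y * b1y + b1z * b1z)
        n2 = np.sqrt(b2x * b2x + b2y * b2y + b2z * b2z)
        c = (b1x * b2x + b1y * b2y + b1z * b2z) / (n1 * n2)
        if c > 1.0:
            c = 1.0
        if c < -1.0:
            c = -1.0
        e += kappa * (1.0 - c)
    if np.isfinite(diameter):
        radius = 0.5 * diameter
        rc = TWO_16 * sig
        for i in range(n):
            rho = np.sqrt(pos[i, 1] * pos[i, 1] + pos[i, 2] * pos[i, 2])
            gap = radius - rho
            if gap <= 0.0:
                return np.inf
            if gap < rc:
                s2 = sig2 / (gap * gap)
                s6 = s2 * s2 * s2
                e += 4.0 * eps * (s6 * s6 - s6) + eps
    return e


# ---------------------------------------------------------------------------
# Langevin integration (velocity Verlet + Langevin thermostat)
# ---------------------------------------------------------------------------

@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True, fastmath=True)
def run_langevin(pos, vel, bonds, angles, eps, sig, fene_k, fene_r0,
                 kappa, diameter, period_x, ext_f, mass, gamma, temperature,
                 dt, n_steps, sample_every, samples_out, max_disp=0.0):
    """Integrate ``n_steps`` velocity-Verlet steps in place; store frames
    every ``sample_every`` steps into ``samples_out`` (n_samples, n, 3).

    The Langevin contribution F_L = -m*gamma*v + sqrt(2 kT m gamma / dt) xi
    is evaluated once per step together with the conservative forces
    (LAMMPS convention), so the same total force enters the second half
    kick of one step and the first half kick of the next; this satisfies
    fluctuation-dissipation at O(dt).  With gamma == 0 the integrator is
    plain symplectic velocity Verlet.  A Verlet neighbor list with skin is
    rebuilt whenever a bead moved more than half the skin.  A positive
    ``max_disp`` caps the per-step displacement of every bead (soft-start
    push-off for initial states with steric overlaps or compressed
    bonds); production runs leave it at zero.

    Returns (status, n_samples_written).
    """
    n = pos.shape[0]
    skin = 0.4 * sig
    cutoff = TWO_16 * sig + skin
    cap = max(64, 60 * n)
    pairs = np.empty((cap, 2), dtype=np.int64)
    n_pairs = build_pairs(pos, period_x, cutoff, pairs)
    if n_pairs > cap:
        return 3, 0
    pos_ref = pos.copy()

    f = np.empty((n, 3))
    status = compute_forces_nl(pos, pairs, n_pairs, bonds, angles, eps, sig,
                               fene_k, fene_r0, kappa, diameter, period_x,
                               ext_f, f)
    if status != 0:
        return status, 0
    noise_amp = np.sqrt(2.0 * temperature * mass * gamma / dt)
    if gamma > 0.0:
        for i in range(n):
            for d in range(3):
                f[i, d] += -mass * gamma * vel[i, d] + \
                    noise_amp * np.random.standard_normal()
    inv_m = 1.0 / mass
    half_dt = 0.5 * dt
    half_skin2 = (0.5 * skin) ** 2
    written = 0
    vcap = max_disp / dt if max_disp > 0.0 else 0.0
    for step in range(n_steps):
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * f[i, d] * inv_m
            if vcap > 0.0:
                vmag = np.sqrt(vel[i, 0] ** 2 + vel[i, 1] ** 2 + vel[i, 2] ** 2)
                if vmag > vcap:
                    sc = vcap / vmag
                    vel[i, 0] *= sc
                    vel[i, 1] *= sc
                    vel[i, 2] *= sc
            for d in range(3):
                pos[i, d] += dt * vel[i, d]
        # rebuild neighbor list if any bead moved more than skin/2
        max_d2 = 0.0
        for i in range(n):
            dxx = pos[i, 0] - pos_ref[i, 0]
            dyy = pos[i, 1] - pos_ref[i, 1]
            dzz = pos[i, 2] - pos_ref[i, 2]
            d2 = dxx * dxx + dyy * dyy + dzz * dzz
            if d2 > max_d2:
                max_d2 = d2
        if max_d2 > half_skin2:
            n_pairs = build_pairs(pos, period_x, cutoff, pairs)
            if n_pairs > cap:
                return 3, written
            pos_ref[:] = pos
        status = compute_forces_nl(pos, pairs, n_pairs, bonds, angles, eps,
                                   sig, fene_k, fene_r0, kappa, diameter,
                                   period_x, ext_f, f)
        if status != 0:
            return status, written
        if gamma > 0.0:
            for i in range(n):
                for d in range(3):
                    f[i, d] += -mass * gamma * vel[i, d] + \
                        noise_amp * np.random.standard_normal()
        for i in range(n):
            for d in range(3):
                vel[i, d] += half_dt * f[i, d] * inv_m
        if sample_every > 0 and (step + 1) % sample_every == 0:
            if written < samples_out.shape[0]:
                for i in range(n):
                    samples_out[written, i, 0] = pos[i, 0]
                    samples_out[written, i, 1] = pos[i, 1]
                    samples_out[written, i, 2] = pos[i, 2]
                written += 1
    for i in range(n):
        for d in range(3):
            if not np.isfinite(pos[i, d]):
                return 3, written
    return 0, written


# ---------------------------------------------------------------------------
# Gauss linking number
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def _segment_pair_omega(p1x, p1y, p1z, p2x, p2y, p2z,
                        q1x, q1y, q1z, q2x, q2y, q2z):
    """Signed solid angle / 4pi contributed by segment pair (p1->p2, q1->q2).

    Klenin & Langowski method 1a: the Gauss integral over a pair of straight
    segments equals the (signed) area of the spherical quadrangle spanned by
    the four connecting directions.
    """
    r13x = q1x - p1x
    r13y = q1y - p1y
    r13z = q1z - p1z
    r14x = q2x - p1x
    r14y = q2y - p1y
    r14z = q2z - p1z
    r23x = q1x - p2x
    r23y = q1y - p2y
    r23z = q1z - p2z
    r24x = q2x - p2x
    r24y = q2y - p2y
    r24z = q2z - p2z

    # n1 = r13 x r14, n2 = r14 x r24, n3 = r24 x r23, n4 = r23 x r13
    n1x = r13y * r14z - r13z * r14y
    n1y = r13z * r14x - r13x * r14z
    n1z = r13x * r14y - r13y * r14x
    n2x = r14y * r24z - r14z * r24y
    n2y = r14z * r24x - r14x * r24z
    n2z = r14x * r24y - r14y * r24x
    n3x = r24y * r23z - r24z * r23y
    n3y = r24z * r23x - r24x * r23z
    n3z = r24x * r23y - r24y * r23x
    n4x = r23y * r13z - r23z * r13y
    n4y = r23z * r13x - r23x * r13z
    n4z = r23x * r13y - r23y * r13x

    m1 = np.sqrt(n1x * n1x + n1y * n1y + n1z * n1z)
    m2 = np.sqrt(n2x * n2x + n2y * n2y + n2z * n2z)
    m3 = np.sqrt(n3x * n3x + n3y * n3y + n3z * n3z)
    m4 = np.sqrt(n4x * n4x + n4y * n4y + n4z * n4z)
    if m1 < 1e-14 or m2 < 1e-14 or m3 < 1e-14 or m4 < 1e-14:
        return 0.0
    n1x /= m1
    n1y /= m1
    n1z /= m1
    n2x /= m2
    n2y /= m2
    n2z /= m2
    n3x /= m3
    n3y /= m3
    n3z /= m3
    n4x /= m4
    n4y /= m4
    n4z /= m4

    d12 = n1x * n2x + n1y * n2y + n1z * n2z
    d23 = n2x * n3x + n2y * n3y + n2z * n3z
    d34 = n3x * n4x + n3y * n4y + n3z * n4z
    d41 = n4x * n1x + n4y * n1y + n4z * n1z
    for _ in range(1):
        if d12 > 1.0:
            d12 = 1.0
        if d12 < -1.0:
            d12 = -1.0
        if d23 > 1.0:
            d23 = 1.0
        if d23 < -1.0:
            d23 = -1.0
        if d34 > 1.0:
            d34 = 1.0
        if d34 < -1.0:
            d34 = -1.0
        if d41 > 1.0:
            d41 = 1.0
        if d41 < -1.0:
            d41 = -1.0
    omega = np.arcsin(d12) + np.arcsin(d23) + np.arcsin(d34) + np.arcsin(d41)

    # sign from (r34 x r12) . r13
    r12x = p2x - p1x
    r12y = p2y - p1y
    r12z = p2z - p1z
    r34x = q2x - q1x
    r34y = q2y - q1y
    r34z = q2z - q1z
    cx = r34y * r12z - r34z * r12y
    cy = r34z * r12x - r34x * r12z
    cz = r34x * r12y - r34y * r12x
    s = cx * r13x + cy * r13y + cz * r13z
    if s > 0.0:
        return omega / (4.0 * np.pi)
    elif s < 0.0:
        return -omega / (4.0 * np.pi)
    return 0.0


@njit(cache=True, fastmath=True)
def gauss_linking_sum(r1, r2):
    """Discrete Gauss double sum over all segment pairs of two closed curves."""
    n1 = r1.shape[0]
    n2 = r2.shape[0]
    total = 0.0
    for i in range(n1):
        i2 = (i + 1) % n1
        for j in range(n2):
            j2 = (j + 1) % n2
            total += _segment_pair_omega(
                r1[i, 0], r1[i, 1], r1[i, 2], r1[i2, 0], r1[i2, 1], r1[i2, 2],
                r2[j, 0], r2[j, 1], r2[j, 2], r2[j2, 0], r2[j2, 1], r2[j2, 2])
    return total


@njit(cache=True, fastmath=True)
def gauss_pair_matrix(r1, r2, out):
    """Per-segment-pair Gauss contributions; out[i, j] for segments i of r1
    and j of r2 (both curves closed)."""
    n1 = r1.shape[0]
    n2 = r2.shape[0]
    for i in range(n1):
        i2 = (i + 1) % n1
        for j in range(n2):
            j2 = (j + 1) % n2
            out[i, j] = _segment_pair_omega(
                r1[i, 0], r1[i, 1], r1[i, 2], r1[i2, 0], r1[i2, 1], r1[i2, 2],
                r2[j, 0], r2[j, 1], r2[j, 2], r2[j2, 0], r2[j2, 1], r2[j2, 2])


@njit(cache=True, fastmath=True)
def open_curves_linking(a, b):
    """Gauss sum for two OPEN polylines (consecutive vertices; no closure)."""
    na = a.shape[0]
    nb = b.shape[0]
    total = 0.0
    for i in range(na - 1):
        for j in range(nb - 1):
            total += _segment_pair_omega(
                a[i, 0], a[i, 1], a[i, 2], a[i + 1, 0], a[i + 1, 1], a[i + 1, 2],
                b[j, 0], b[j, 1], b[j, 2], b[j + 1, 0], b[j + 1, 1], b[j + 1, 2])
    return total


# ---------------------------------------------------------------------------
# Planar crossing detection
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def find_crossings(p2d, depth, seg_start, seg_end, seg_comp,
                   out_a, out_b, out_sign, out_over_first, out_ta, out_tb):
    """All transversal crossings between projected segments.

    p2d: (n, 2) projected vertex coordinates, depth: (n,) coordinate along
    the projection direction.  Segments are seg_start[k] -> seg_end[k]
    (vertex indices) belonging to component seg_comp[k].  Adjacent segments
    (sharing a vertex) are skipped.  Returns the number of crossings found;
    records: segment indices a < b, crossing sign (right-handed convention
    for the pair (tangent_over, tangent_under)), whether segment a is the
    over strand, and the intersection parameters along a and b.
    """
    ns = seg_start.shape[0]
    count = 0
    cap = out_a.shape[0]
    for i in range(ns):
        a0 = seg_start[i]
        a1 = seg_end[i]
        ax = p2d[a0, 0]
        ay = p2d[a0, 1]
        bx = p2d[a1, 0]
        by = p2d[a1, 1]
        dax = bx - ax
        day = by - ay
        for j in range(i + 1, ns):
            b0 = seg_start[j]
            b1 = seg_end[j]
            if a0 == b0 or a0 == b1 or a1 == b0 or a1 == b1:
                continue
            cx = p2d[b0, 0]
            cy = p2d[b0, 1]
            dx_ = p2d[b1, 0]
            dy_ = p2d[b1, 1]
            dbx = dx_ - cx
            dby = dy_ - cy
            denom = dax * dby - day * dbx
            if denom == 0.0:
                continue
            tx = cx - ax
            ty = cy - ay
            t = (tx * dby - ty * dbx) / denom
            u = (tx * day - ty * dax) / denom
            if t <= 0.0 or t >= 1.0 or u <= 0.0 or u >= 1.0:
                continue
            # depth at intersection along each segment
            za = depth[a0] + t * (depth[a1] - depth[a0])
            zb = depth[b0] + u * (depth[b1] - depth[b0])
            if za == zb:
                continue
            a_over = za > zb
            # sign: z-component of (tangent_over x tangent_under)
            if a_over:
                cross = dax * dby - day * dbx
            else:
                cross = dbx * day - dby * dax
            s = 1 if cross > 0.0 else -1
            if count < cap:
                out_a[count] = i
                out_b[count] = j
                out_sign[count] = s
                out_over_first[count] = 1 if a_over else 0
                out_ta[count] = t
                out_tb[count] = u
            count += 1
    return count


# ---------------------------------------------------------------------------
# Physical-link (shortest linked arcs) search support
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def closure_lk_terms(arc, other, cpt):
    """Gauss terms between the two closure segments of ``arc`` (end->cpt,
    cpt->start) and all segments of the *closed* polyline ``other`` plus the
    closure of the other arc is handled by the caller; here ``other`` is an
    open polyline of vertices and the terms are summed against its
    consecutive segments only."""
    total = 0.0
    n = other.shape[0]
    e = arc.shape[0] - 1
    for j in range(n - 1):
        total += _segment_pair_omega(
            arc[e, 0], arc[e, 1], arc[e, 2], cpt[0], cpt[1], cpt[2],
            other[j, 0], other[j, 1], other[j, 2],
            other[j + 1, 0], other[j + 1, 1], other[j + 1, 2])
        total += _segment_pair_omega(
            cpt[0], cpt[1], cpt[2], arc[0, 0], arc[0, 1], arc[0, 2],
            other[j, 0], other[j, 1], other[j, 2],
            other[j + 1, 0], other[j + 1, 1], other[j + 1, 2])
    return total


@njit(cache=True, fastmath=True)
def arc_pair_linking(r1, r2, s1, l1, s2, l2, cpt1, cpt2):
    """Linking number (float) of closed(arc1) and closed(arc2).

    Arc k starts at bead s_k and spans l_k beads (l_k - 1 segments) of the
    cyclic curve r_k; each arc is closed through its own far point cpt_k.
    """
    n1 = r1.shape[0]
    n2 = r2.shape[0]
    a1 = np.empty((l1, 3))
    a2 = np.empty((l2, 3))
    for i in range(l1):
        idx = (s1 + i) % n1
        a1[i, 0] = r1[idx, 0]
        a1[i, 1] = r1[idx, 1]
        a1[i, 2] = r1[idx, 2]
    for i in range(l2):
        idx = (s2 + i) % n2
        a2[i, 0] = r2[idx, 0]
        a2[i, 1] = r2[idx, 1]
        a2[i, 2] = r2[idx, 2]
    total = open_curves_linking(a1, a2)
    # closure segments of arc1 against open arc2
    e1 = l1 - 1
    for j in range(l2 - 1):
        total += _segment_pair_omega(
            a1[e1, 0], a1[e1, 1], a1[e1, 2], cpt1[0], cpt1[1], cpt1[2],
            a2[j, 0], a2[j, 1], a2[j, 2], a2[j + 1, 0], a2[j + 1, 1], a2[j + 1, 2])
        total += _segment_pair_omega(
            cpt1[0], cpt1[1], cpt1[2], a1[0, 0], a1[0, 1], a1[0, 2],
            a2[j, 0], a2[j, 1], a2[j, 2], a2[j + 1, 0], a2[j + 1, 1], a2[j + 1, 2])
    # closure of arc2 against the fully closed arc1 (including its closure)
    e2 = l2 - 1
    closed1 = np.empty((l1 + 3, 3))
    for i in range(l1):
        closed1[i] = a1[i]
    closed1[l1] = cpt1
    closed1[l1 + 1] = a1[0]
    # the polyline closed1[0..l1+1] traverses arc1 then closure; last point
    # repeats the start so consecutive-segment iteration covers everything
    for j in range(l1 + 1):
        total += _segment_pair_omega(
            closed1[j, 0], closed1[j, 1], closed1[j, 2],
            closed1[j + 1, 0], closed1[j + 1, 1], closed1[j + 1, 2],
            a2[e2, 0], a2[e2, 1], a2[e2, 2], cpt2[0], cpt2[1], cpt2[2])
        total += _segment_pair_omega(
            closed1[j, 0], closed1[j, 1], closed1[j, 2],
            closed1[j + 1, 0], closed1[j + 1, 1], closed1[j + 1, 2],
            cpt2[0], cpt2[1], cpt2[2], a2[0, 0], a2[0, 1], a2[0, 2])
    return total


# ---------------------------------------------------------------------------
# Misc small kernels
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True)
def min_segment_gap(r1, r2):
    """Minimum distance between any bead of r1 and any bead of r2."""
    best = 1e300
    for i in range(r1.shape[0]):
        for j in range(r2.shape[0]):
            dx = r1[i, 0] - r2[j, 0]
            dy = r1[i, 1] - r2[j, 1]
            dz = r1[i, 2] - r2[j, 2]
            d2 = dx * dx + dy * dy + dz * dz
            if d2 < best:
                best = d2
    return np.sqrt(best)


@njit(cache=True, fastmath=True)
def _seg_omega_pts(a0, a1, b0, b1):
    return _segment_pair_omega(a0[0], a0[1], a0[2], a1[0], a1[1], a1[2],
                               b0[0], b0[1], b0[2], b1[0], b1[1], b1[2])


@njit(cache=True, fastmath=True)
def precompute_arc_linking(r1, r2, cpt1, cpt2):
    """Precomputed Gauss-term tables for the O(1)-per-candidate arc scan.

    Returns (P, C1out, C1in, C2out, C2in):
      P        -- 2D prefix sums of the segment-pair Gauss terms on the
                  doubled (wrap-aware) index grid;
      C1out/in -- prefix sums over ring-2 segments of the terms against the
                  closure segments (bead b -> cpt1) / (cpt1 -> bead b);
      C2out/in -- same with the roles of the rings swapped.
    """
    n1 = r1.shape[0]
    n2 = r2.shape[0]
    g = np.empty((2 * n1, 2 * n2))
    for i in range(n1):
        i2 = (i + 1) % n1
        for j in range(n2):
            j2 = (j + 1) % n2
            v = _segment_pair_omega(
                r1[i, 0], r1[i, 1], r1[i, 2], r1[i2, 0], r1[i2, 1], r1[i2, 2],
                r2[j, 0], r2[j, 1], r2[j, 2], r2[j2, 0], r2[j2, 1], r2[j2, 2])
            g[i, j] = v
            g[i + n1, j] = v
            g[i, j + n2] = v
            g[i + n1, j + n2] = v
    p = np.zeros((2 * n1 + 1, 2 * n2 + 1))
    for i in range(2 * n1):
        row = 0.0
        for j in range(2 * n2):
            row += g[i, j]
            p[i + 1, j + 1] = p[i, j + 1] + row

    c1out = np.zeros((n1, 2 * n2 + 1))
    c1in = np.zeros((n1, 2 * n2 + 1))
    for b in range(n1):
        for j in range(n2):
            j2 = (j + 1) % n2
            vout = _segment_pair_omega(
                r1[b, 0], r1[b, 1], r1[b, 2], cpt1[0], cpt1[1], cpt1[2],
                r2[j, 0], r2[j, 1], r2[j, 2], r2[j2, 0], r2[j2, 1], r2[j2, 2])
            vin = _segment_pair_omega(
                cpt1[0], cpt1[1], cpt1[2], r1[b, 0], r1[b, 1], r1[b, 2],
                r2[j, 0], r2[j, 1], r2[j, 2], r2[j2, 0], r2[j2, 1], r2[j2, 2])
            c1out[b, j + 1] = c1out[b, j] + vout
            c1in[b, j + 1] = c1in[b, j] + vin
        for j in range(n2, 2 * n2):
            c1out[b, j + 1] = c1out[b, j] + c1out[b, j - n2 + 1] - c1out[b, j - n2]
            c1in[b, j + 1] = c1in[b, j] + c1in[b, j - n2 + 1] - c1in[b, j - n2]

    c2out = np.zeros((n2, 2 * n1 + 1))
    c2in = np.zeros((n2, 2 * n1 + 1))
    for b in range(n2):
        for i in range(n1):
            i2 = (i + 1) % n1
            vout = _segment_pair_omega(
                r1[i, 0], r1[i, 1], r1[i, 2], r1[i2, 0], r1[i2, 1], r1[i2, 2],
                r2[b, 0], r2[b, 1], r2[b, 2], cpt2[0], cpt2[1], cpt2[2])
            vin = _segment_pair_omega(
                r1[i, 0], r1[i, 1], r1[i, 2], r1[i2, 0], r1[i2, 1], r1[i2, 2],
                cpt2[0], cpt2[1], cpt2[2], r2[b, 0], r2[b, 1], r2[b, 2])
            c2out[b, i + 1] = c2out[b, i] + vout
            c2in[b, i + 1] = c2in[b, i] + vin
        for i in range(n1, 2 * n1):
            c2out[b, i + 1] = c2out[b, i] + c2out[b, i - n1 + 1] - c2out[b, i - n1]
            c2in[b, i + 1] = c2in[b, i] + c2in[b, i - n1 + 1] - c2in[b, i - n1]
    return p, c1out, c1in, c2out, c2in


@njit(cache=True, fastmath=True)
def arc_pair_linking_fast(r1, r2, s1, l1, s2, l2, cpt1, cpt2,
                          p, c1out, c1in, c2out, c2in):
    """Linking number of closed(arc1), closed(arc2) from precomputed
    tables; O(1) plus four direct closure-closure terms."""
    n1 = r1.shape[0]
    n2 = r2.shape[0]
    e1 = (s1 + l1 - 1) % n1   # last bead of arc1 (closure leaves from here)
    e2 = (s2 + l2 - 1) % n2
    da = l1 - 1               # interior segment counts
    db = l2 - 1
    # interior x interior via 2D prefix
    total = (p[s1 + da, s2 + db] - p[s1, s2 + db]
             - p[s1 + da, s2] + p[s1, s2])
    # closure segments of arc1 vs interior of arc2
    total += c1out[e1, s2 + db] - c1out[e1, s2]
    total += c1in[s1 % n1, s2 + db] - c1in[s1 % n1, s2]
    # closure segments of arc2 vs interior of arc1
    total += c2out[e2, s1 + da] - c2out[e2, s1]
    total += c2in[s2 % n2, s1 + da] - c2in[s2 % n2, s1]
    # closure x closure (4 direct terms)
    total += _seg_omega_pts(r1[e1], cpt1, r2[e2], cpt2)
    total += _seg_omega_pts(r1[e1], cpt1, cpt2, r2[s2 % n2])
    total += _seg_omega_pts(cpt1, r1[s1 % n1], r2[e2], cpt2)
    total += _seg_omega_pts(cpt1, r1[s1 % n1], cpt2, r2[s2 % n2])
    return total


@njit(cache=True, fastmath=True)
def candidate_scan_fast(r1, r2, lk_target, starts1, starts2, cpt1, cpt2,
                        total_len, min_arc, p, c1out, c1in, c2out, c2in,
                        out_s1, out_l1, out_s2, out_l2):
    """Like candidate_scan but using the precomputed prefix tables."""
    cap = out_s1.shape[0]
    count = 0
    n1 = r1.shape[0]
    n2 = r2.shape[0]
    max_d = total_len - 2 * min_arc
    for d in range(0, max_d + 1):
        for sgn in range(2):
            if d == 0 and sgn == 1:
                continue
            if sgn == 0:
                if (total_len + d) % 2 != 0:
                    continue
                l1 = (total_len + d) // 2
            else:
                if (total_len - d) % 2 != 0:
                    continue
                l1 = (total_len - d) // 2
            l2 = total_len - l1
            if l1 < min_arc or l2 < min_arc or l1 > n1 or l2 > n2:
                continue
            for a in range(starts1.shape[0]):
                s1 = starts1[a]
                for b in range(starts2.shape[0]):
                    s2 = starts2[b]
                    lk = arc_pair_linking_fast(r1, r2, s1, l1, s2, l2,
                                               cpt1, cpt2, p, c1out, c1in,
                                               c2out, c2in)
                    ilk = int(np.round(lk))
                    if ilk == lk_target and np.abs(lk - ilk) < 0.25:
                        if count < cap:
                            out_s1[count] = s1
                            out_l1[count] = l1
                            out_s2[count] = s2
                            out_l2[count] = l2
                        count += 1
    return count
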