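"""Numba hot loops for the finite-element growth solver.

These kernels mirror the reference numpy implementations in ``mechanics``
(``element_response``, ``contact_forces``, ``step``); the test suite checks
the two routes against each other.  All state is passed explicitly so the
loops stay allocation-free; matrices are 3x3 and hand-unrolled.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def assemble_elastic(pos, tets, Bm, Ginv, Vg, mu, lam, forces):
    """Accumulate nodal elastic forces; return (energy, min_Je).

    ``forces`` must be zeroed by the caller.  A non-positive elastic
    Jacobian short-circuits with ``min_Je <= 0`` so the caller can abort.
    """
    energy = 0.0
    min_je = 1.0e300
    for e in range(tets.shape[0]):
        i0 = tets[e, 0]
        i1 = tets[e, 1]
        i2 = tets[e, 2]
        i3 = tets[e, 3]
        # deformed shape matrix Ds (columns = edge vectors from node 0)
        d00 = pos[i1, 0] - pos[i0, 0]
        d10 = pos[i1, 1] - pos[i0, 1]
        d20 = pos[i1, 2] - pos[i0, 2]
        d01 = pos[i2, 0] - pos[i0, 0]
        d11 = pos[i2, 1] - pos[i0, 1]
        d21 = pos[i2, 2] - pos[i0, 2]
        d02 = pos[i3, 0] - pos[i0, 0]
        d12 = pos[i3, 1] - pos[i0, 1]
        d22 = pos[i3, 2] - pos[i0, 2]
        b = Bm[e]
        # F = Ds @ B
        f00 = d00 * b[0, 0] + d01 * b[1, 0] + d02 * b[2, 0]
        f01 = d00 * b[0, 1] + d01 * b[1, 1] + d02 * b[2, 1]
        f02 = d00 * b[0, 2] + d01 * b[1, 2] + d02 * b[2, 2]
        f10 = d10 * b[0, 0] + d11 * b[1, 0] + d12 * b[2, 0]
        f11 = d10 * b[0, 1] + d11 * b[1, 1] + d12 * b[2, 1]
        f12 = d10 * b[0, 2] + d11 * b[1, 2] + d12 * b[2, 2]
        f20 = d20 * b[0, 0] + d21 * b[1, 0] + d22 * b[2, 0]
        f21 = d20 * b[0, 1] + d21 * b[1, 1] + d22 * b[2, 1]
        f22 = d20 * b[0, 2] + d21 * b[1, 2] + d22 * b[2, 2]
        g = Ginv[e]
        # Fe = F @ Ginv (Ginv symmetric)
        e00 = f00 * g[0, 0] + f01 * g[1, 0] + f02 * g[2, 0]
        e01 = f00 * g[0, 1] + f01 * g[1, 1] + f02 * g[2, 1]
        e02 = f00 * g[0, 2] + f01 * g[1, 2] + f02 * g[2, 2]
        e10 = f10 * g[0, 0] + f11 * g[1, 0] + f12 * g[2, 0]
        e11 = f10 * g[0, 1] + f11 * g[1, 1] + f12 * g[2, 1]
        e12 = f10 * g[0, 2] + f11 * g[1, 2] + f12 * g[2, 2]
        e20 = f20 * g[0, 0] + f21 * g[1, 0] + f22 * g[2, 0]
        e21 = f20 * g[0, 1] + f21 * g[1, 1] + f22 * g[2, 1]
        e22 = f20 * g[0, 2] + f21 * g[1, 2] + f22 * g[2, 2]
        # Je = det(Fe)
        c00 = e11 * e22 - e12 * e21
        c01 = e12 * e20 - e10 * e22
        c02 = e10 * e21 - e11 * e20
        je = e00 * c00 + e01 * c01 + e02 * c02
        if je < min_je:
            min_je = je
        if je <= 0.0:
            return energy, min_je
        # inverse of Fe via adjugate
        inv = 1.0 / je
        n00 = c00 * inv
        n10 = c01 * inv
        n20 = c02 * inv
        n01 = (e02 * e21 - e01 * e22) * inv
        n11 = (e00 * e22 - e02 * e20) * inv
        n21 = (e01 * e20 - e00 * e21) * inv
        n02 = (e01 * e12 - e02 * e11) * inv
        n12 = (e02 * e10 - e00 * e12) * inv
        n22 = (e00 * e11 - e01 * e10) * inv
        lnj = np.log(je)
        m = mu[e]
        la = lam[e]
        s = la * lnj - m
        # first Piola-Kirchhoff wrt Fe: P = mu*Fe + (lam*lnJ - mu) * Fe^{-T}
        p00 = m * e00 + s * n00
        p01 = m * e01 + s * n10
        p02 = m * e02 + s * n20
        p10 = m * e10 + s * n01
        p11 = m * e11 + s * n11
        p12 = m * e12 + s * n21
        p20 = m * e20 + s * n02
        p21 = m * e21 + s * n12
        p22 = m * e22 + s * n22
        # Q = P @ Ginv  (dW/dF)
        q00 = p00 * g[0, 0] + p01 * g[1, 0] + p02 * g[2, 0]
        q01 = p00 * g[0, 1] + p01 * g[1, 1] + p02 * g[2, 1]
        q02 = p00 * g[0, 2] + p01 * g[1, 2] + p02 * g[2, 2]
        q10 = p10 * g[0, 0] + p11 * g[1, 0] + p12 * g[2, 0]
        q11 = p10 * g[0, 1] + p11 * g[1, 1] + p12 * g[2, 1]
        q12 = p10 * g[0, 2] + p11 * g[1, 2] + p12 * g[2, 2]
        q20 = p20 * g[0, 0] + p21 * g[1, 0] + p22 * g[2, 0]
        q21 = p20 * g[0, 1] + p21 * g[1, 1] + p22 * g[2, 1]
        q22 = p20 * g[0, 2] + p21 * g[1, 2] + p22 * g[2, 2]
        vg = Vg[e]
        # H = Vg * Q @ B^T ; column c is dE/d(x_{c+1})
        h00 = vg * (q00 * b[0, 0] + q01 * b[0, 1] + q02 * b[0, 2])
        h01 = vg * (q00 * b[1, 0] + q01 * b[1, 1] + q02 * b[1, 2])
        h02 = vg * (q00 * b[2, 0] + q01 * b[2, 1] + q02 * b[2, 2])
        h10 = vg * (q10 * b[0, 0] + q11 * b[0, 1] + q12 * b[0, 2])
        h11 = vg * (q10 * b[1, 0] + q11 * b[1, 1] + q12 * b[1, 2])
        h12 = vg * (q10 * b[2, 0] + q11 * b[2, 1] + q12 * b[2, 2])
        h20 = vg * (q20 * b[0, 0] + q21 * b[0, 1] + q22 * b[0, 2])
        h21 = vg * (q20 * b[1, 0] + q21 * b[1, 1] + q22 * b[1, 2])
        h22 = vg * (q20 * b[2, 0] + q21 * b[2, 1] + q22 * b[2, 2])
        forces[i1, 0] -= h00
        forces[i1, 1] -= h10
        forces[i1, 2] -= h20
        forces[i2, 0] -= h01
        forces[i2, 1] -= h11
        forces[i2, 2] -= h21
        forces[i3, 0] -= h02
        forces[i3, 1] -= h12
        forces[i3, 2] -= h22
        forces[i0, 0] += h00 + h01 + h02
        forces[i0, 1] += h10 + h11 + h12
        forces[i0, 2] += h20 + h21 + h22
        # strain energy density
        i1c = (e00 * e00 + e01 * e01 + e02 * e02
               + e10 * e10 + e11 * e11 + e12 * e12
               + e20 * e20 + e21 * e21 + e22 * e22)
        energy += vg * (0.5 * m * (i1c - 3.0) - m * lnj + 0.5 * la * lnj * lnj)
    return energy, min_je


@njit(cache=True)
def _closest_point_triangle(px, py, pz, ax, ay, az, bx, by, bz, cx, cy, cz):
    """Closest point on triangle abc to p; returns (qx, qy, qz, u, v, w)."""
    abx = bx - ax
    aby = by - ay
    abz = bz - az
    acx = cx - ax
    acy = cy - ay
    acz = cz - az
    apx = px - ax
    apy = py - ay
    apz = pz - az
    d1 = abx * apx + aby * apy + abz * apz
    d2 = acx * apx + acy * apy + acz * apz
    if d1 <= 0.0 and d2 <= 0.0:
        return ax, ay, az, 1.0, 0.0, 0.0
    bpx = px - bx
    bpy = py - by
    bpz = pz - bz
    d3 = abx * bpx + aby * bpy + abz * bpz
    d4 = acx * bpx + acy * bpy + acz * bpz
    if d3 >= 0.0 and d4 <= d3:
        return bx, by, bz, 0.0, 1.0, 0.0
    vc = d1 * d4 - d3 * d2
    if vc <= 0.0 and d1 >= 0.0 and d3 <= 0.0:
        t = d1 / (d1 - d3)
        return (ax + t * abx, ay + t * aby, az + t * abz,
                1.0 - t, t, 0.0)
    cpx = px - cx
    cpy = py - cy
    cpz = pz - cz
    d5 = abx * cpx + aby * cpy + abz * cpz
    d6 = acx * cpx + acy * cpy + acz * cpz
    if d6 >= 0.0 and d5 <= d6:
        return cx, cy, cz, 0.0, 0.0, 1.0
    vb = d5 * d2 - d1 * d6
    if vb <= 0.0 and d2 >= 0.0 and d6 <= 0.0:
        t = d2 / (d2 - d6)
        return (ax + t * acx, ay + t * acy, az + t * acz,
                1.0 - t, 0.0, t)
    va = d3 * d6 - d5 * d4
    if va <= 0.0 and (d4 - d3) >= 0.0 and (d5 - d6) >= 0.0:
        t = (d4 - d3) / ((d4 - d3) + (d5 - d6))
        return (bx + t * (cx - bx), by + t * (cy - by), bz + t * (cz - bz),
                0.0, 1.0 - t, t)
    denom = 1.0 / (va + vb + vc)
    v = vb * denom
    w = vc * denom
    return (ax + abx * v + acx * w, ay + aby * v + acy * w,
            az + abz * v + acz * w, 1.0 - v - w, v, w)


@njit(cache=True)
def add_contact(pos, pair_nodes, pair_tris, k_con, r_con, forces):
    """Node-triangle penalty forces for precomputed candidate pairs.

    Equal and opposite: the node's repulsion is balanced by barycentric
    loads on the triangle vertices.  Returns the contact penalty energy.
    """
    energy = 0.0
    for p in range(pair_nodes.shape[0]):
        i = pair_nodes[p]
        a = pair_tris[p, 0]
        b = pair_tris[p, 1]
        c = pair_tris[p, 2]
        qx, qy, qz, u, v, w = _closest_point_triangle(
            pos[i, 0], pos[i, 1], pos[i, 2],
            pos[a, 0], pos[a, 1], pos[a, 2],
            pos[b, 0], pos[b, 1], pos[b, 2],
            pos[c, 0], pos[c, 1], pos[c, 2],
        )
        dx = pos[i, 0] - qx
        dy = pos[i, 1] - qy
        dz = pos[i, 2] - qz
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < r_con and d > 1e-12:
            fm = k_con * (r_con - d) / d
            fx = fm * dx
            fy = fm * dy
            fz = fm * dz
            forces[i, 0] += fx
            forces[i, 1] += fy
            forces[i, 2] += fz
            forces[a, 0] -= u * fx
            forces[a, 1] -= u * fy
            forces[a, 2] -= u * fz
            forces[b, 0] -= v * fx
            forces[b, 1] -= v * fy
            forces[b, 2] -= v * fz
            forces[c, 0] -= w * fx
            forces[c, 1] -= w * fy
            forces[c, 2] -= w * fz
            energy += 0.5 * k_con * (r_con - d) ** 2
    return energy


@njit(cache=True)
def relax_chunk(pos, vel, tets, Bm, Ginv, Vg, mu, lam, mass, constraint,
                pair_nodes, pair_tris, k_con, r_con,
                dt, damp, nsteps, ftol, forces):
    """Damped semi-implicit Euler steps at fixed growth.

    Runs up to ``nsteps`` steps, stopping early once the constraint-projected
    residual force maximum falls below ``ftol``.  Returns
    (steps_taken, residual, min_Je, elastic_energy, contact_energy,
    max_speed, inverted).
    """
    n = pos.shape[0]
    steps = 0
    res = 1.0e300
    min_je = 1.0e300
    en = 0.0
    cen = 0.0
    max_speed = 0.0
    decay = 1.0 - damp * dt
    if decay < 0.0:
        decay = 0.0
    for s in range(nsteps):
        for i in range(n):
            forces[i, 0] = 0.0
            forces[i, 1] = 0.0
            forces[i, 2] = 0.0
        en, min_je = assemble_elastic(pos, tets, Bm, Ginv, Vg, mu, lam, forces)
        if min_je <= 0.0:
            return steps, res, min_je, en, cen, max_speed, True
        cen = 0.0
        if k_con > 0.0 and pair_nodes.shape[0] > 0:
            cen = add_contact(pos, pair_nodes, pair_tris, k_con, r_con, forces)
        # projected residual
        res = 0.0
        for i in range(n):
            ci = constraint[i]
            fx = ci[0, 0] * forces[i, 0] + ci[0, 1] * forces[i, 1] + ci[0, 2] * forces[i, 2]
            fy = ci[1, 0] * forces[i, 0] + ci[1, 1] * forces[i, 1] + ci[1, 2] * forces[i, 2]
            fz = ci[2, 0] * forces[i, 0] + ci[2, 1] * forces[i, 1] + ci[2, 2] * forces[i, 2]
            fn = np.sqrt(fx * fx + fy * fy + fz * fz)
            if fn > res:
                res = fn
        if res < ftol:
            return steps, res, min_je, en, cen, max_speed, False
        max_speed = 0.0
        for i in range(n):
            mi = mass[i]
            if mi <= 0.0:
                continue
            vx = (vel[i, 0] + dt * forces[i, 0] / mi) * decay
            vy = (vel[i, 1] + dt * forces[i, 1] / mi) * decay
            vz = (vel[i, 2] + dt * forces[i, 2] / mi) * decay
            ci = constraint[i]
            px = ci[0, 0] * vx + ci[0, 1] * vy + ci[0, 2] * vz
            py = ci[1, 0] * vx + ci[1, 1] * vy + ci[1, 2] * vz
            pz = ci[2, 0] * vx + ci[2, 1] * vy + ci[2, 2] * vz
            vel[i, 0] = px
            vel[i, 1] = py
            vel[i, 2] = pz
            sp = np.sqrt(px * px + py * py + pz * pz)
            if sp > max_speed:
                max_speed = sp
            pos[i, 0] += dt * px
            pos[i, 1] += dt * py
            pos[i, 2] += dt * pz
        steps += 1
    return steps, res, min_je, en, cen, max_speed, False
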