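"""McMurchie-Davidson evaluation of Gaussian integrals (numba kernels).

All quantities here are in atomic units.  Shells are passed as flat arrays;
the public wrappers live in :mod:`mlccx.integrals`.

The Hermite expansion coefficients E_t^{ij} and the Hermite Coulomb
integrals R^n_{tuv} follow the standard McMurchie-Davidson recurrences.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

SQRT_PI = math.sqrt(math.pi)
TWO_PI_POW = 2.0 * math.pi ** 2.5


@njit(cache=True)
def boys(m_max, x, out):
    """Fill out[0..m_max] with Boys functions F_m(x)."""
    if x > 35.0:
        # upward recursion; exp(-x) negligible
        out[0] = 0.5 * math.sqrt(math.pi / x)
        for m in range(1, m_max + 1):
            out[m] = out[m - 1] * (2 * m - 1) / (2.0 * x)
        return
    # non-alternating Kummer series for the highest order, then downward
    m = m_max
    s = 1.0 / (2 * m + 1)
    term = s
    k = 1
    while True:
        term *= 2.0 * x / (2 * m + 2 * k + 1)
        s += term
        if term < 1e-17 * s or k > 300:
            break
        k += 1
    ex = math.exp(-x)
    out[m_max] = ex * s
    for mm in range(m_max, 0, -1):
        out[mm - 1] = (2.0 * x * out[mm] + ex) / (2 * mm - 1)


@njit(cache=True)
def fill_E(l1, l2, a, b, ab, E):
    """1D Hermite expansion coefficients E[i, j, t] for one axis.

    ``ab`` is the A-B distance along this axis; E must have shape at least
    (l1+1, l2+1, l1+l2+1).  E[0,0,0] carries the Gaussian product prefactor.
    """
    p = a + b
    mu = a * b / p
    pa = -(b / p) * ab
    pb = (a / p) * ab
    E[:, :, :] = 0.0
    E[0, 0, 0] = math.exp(-mu * ab * ab)
    for i in range(l1):
        for t in range(i + 2):
            v = pa * E[i, 0, t]
            if t > 0:
                v += E[i, 0, t - 1] / (2.0 * p)
            if t + 1 <= i:
                v += (t + 1) * E[i, 0, t + 1]
            E[i + 1, 0, t] = v
    for i in range(l1 + 1):
        for j in range(l2):
            for t in range(i + j + 2):
                v = pb * E[i, j, t]
                if t > 0:
                    v += E[i, j, t - 1] / (2.0 * p)
                if t + 1 <= i + j:
                    v += (t + 1) * E[i, j, t + 1]
                E[i, j + 1, t] = v


@njit(cache=True)
def fill_R(nmax, tmax, umax, vmax, p, xpc, ypc, zpc, R, fbuf):
    """Hermite Coulomb integrals R[n, t, u, v] for exponent p and P-C."""
    T = p * (xpc * xpc + ypc * ypc + zpc * zpc)
    ntot = nmax
    boys(ntot, T, fbuf)
    fac = 1.0
    for n in range(ntot + 1):
        R[n, 0, 0, 0] = fac * fbuf[n]
        fac *= -2.0 * p
    for t in range(1, tmax + 1):
        for n in range(ntot - t + 1):
            v = xpc * R[n + 1, t - 1, 0, 0]
            if t > 1:
                v += (t - 1) * R[n + 1, t - 2, 0, 0]
            R[n, t, 0, 0] = v
    for u in range(1, umax + 1):
        for t in range(tmax + 1):
            for n in range(ntot - t - u + 1):
                v = ypc * R[n + 1, t, u - 1, 0]
                if u > 1:
                    v += (u - 1) * R[n + 1, t, u - 2, 0]
                R[n, t, u, 0] = v
    for v_ in range(1, vmax + 1):
        for u in range(umax + 1):
            for t in range(tmax + 1):
                for n in range(ntot - t - u - v_ + 1):
                    val = zpc * R[n + 1, t, u, v_ - 1]
                    if v_ > 1:
                        val += (v_ - 1) * R[n + 1, t, u, v_ - 2]
                    R[n, t, u, v_] = val


@njit(cache=True)
def _cart_powers(l, comps):
    k = 0
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            comps[k, 0] = lx
            comps[k, 1] = ly
            comps[k, 2] = l - lx - ly
            k += 1
    return k


@njit(cache=True)
def one_electron(sh_l, sh_np, sh_ps, sh_c, sh_ao, prim_exp, prim_coef,
                 atom_xyz, atom_z, nao, S, T, V):
    """Overlap, kinetic and nuclear-attraction matrices over all shells."""
    nsh = sh_l.shape[0]
    Ex = np.zeros((4, 6, 10))
    Ey = np.zeros((4, 6, 10))
    Ez = np.zeros((4, 6, 10))
    comps1 = np.zeros((10, 3), dtype=np.int64)
    comps2 = np.zeros((10, 3), dtype=np.int64)
    R = np.zeros((6, 6, 6, 6))
    fbuf = np.zeros(10)
    natoms = atom_z.shape[0]
    for ish in range(nsh):
        l1 = sh_l[ish]
        n1 = _cart_powers(l1, comps1)
        for jsh in range(ish + 1):
            l2 = sh_l[jsh]
            n2 = _cart_powers(l2, comps2)
            abx = sh_c[ish, 0] - sh_c[jsh, 0]
            aby = sh_c[ish, 1] - sh_c[jsh, 1]
            abz = sh_c[ish, 2] - sh_c[jsh, 2]
            for ip in range(sh_np[ish]):
                a = prim_exp[sh_ps[ish] + ip]
                ca = prim_coef[sh_ps[ish] + ip]
                for jp in range(sh_np[jsh]):
                    b = prim_exp[sh_ps[jsh] + jp]
                    cb = prim_coef[sh_ps[jsh] + jp]
                    p = a + b
                    # l2+2 for the kinetic energy ladder
                    fill_E(l1, l2 + 2, a, b, abx, Ex)
                    fill_E(l1, l2 + 2, a, b, aby, Ey)
                    fill_E(l1, l2 + 2, a, b, abz, Ez)
                    spre = (math.pi / p) ** 1.5
                    cc = ca * cb
                    px = (a * sh_c[ish, 0] + b * sh_c[jsh, 0]) / p
                    py = (a * sh_c[ish, 1] + b * sh_c[jsh, 1]) / p
                    pz = (a * sh_c[ish, 2] + b * sh_c[jsh, 2]) / p
                    for c1 in range(n1):
                        ix, iy, iz = comps1[c1, 0], comps1[c1, 1], comps1[c1, 2]
                        mu = sh_ao[ish] + c1
                        for c2 in range(n2):
                            jx, jy, jz = comps2[c2, 0], comps2[c2, 1], comps2[c2, 2]
                            nu = sh_ao[jsh] + c2
                            if nu > mu:
                                continue
                            sx = Ex[ix, jx, 0]
                            sy = Ey[iy, jy, 0]
                            sz = Ez[iz, jz, 0]
                            S[mu, nu] += cc * spre * sx * sy * sz
                            # kinetic: per-axis second-derivative ladder
                            tx = -2.0 * b * (2 * jx + 1) * Ex[ix, jx, 0] \
                                + 4.0 * b * b * Ex[ix, jx + 2, 0]
                            if jx >= 2:
                                tx += jx * (jx - 1) * Ex[ix, jx - 2, 0]
                            ty = -2.0 * b * (2 * jy + 1) * Ey[iy, jy, 0] \
                                + 4.0 * b * b * Ey[iy, jy + 2, 0]
                            if jy >= 2:
                                ty += jy * (jy - 1) * Ey[iy, jy - 2, 0]
                            tz = -2.0 * b * (2 * jz + 1) * Ez[iz, jz, 0] \
                                + 4.0 * b * b * Ez[iz, jz + 2, 0]
                            if jz >= 2:
                                tz += jz * (jz - 1) * Ez[iz, jz - 2, 0]
                            T[mu, nu] += -0.5 * cc * spre * (
                                tx * sy * sz + sx * ty * sz + sx * sy * tz
                            )
                            # nuclear attraction via Hermite Coulomb integrals
                            tmax = ix + jx
                            umax = iy + jy
                            vmax = iz + jz
                            for ia in range(natoms):
                                fill_R(tmax + umax + vmax, tmax, umax, vmax, p,
                                       px - atom_xyz[ia, 0],
                                       py - atom_xyz[ia, 1],
                                       pz - atom_xyz[ia, 2], R, fbuf)
                                acc = 0.0
                                for t in range(tmax + 1):
                                    for u in range(umax + 1):
                                        for w in range(vmax + 1):
                                            acc += (Ex[ix, jx, t] * Ey[iy, jy, u]
                                                    * Ez[iz, jz, w] * R[0, t, u, w])
                                V[mu, nu] += -atom_z[ia] * cc * (2.0 * math.pi / p) * acc
    for mu in range(nao):
        for nu in range(mu):
            S[nu, mu] = S[mu, nu]
            T[nu, mu] = T[mu, nu]
            V[nu, mu] = V[mu, nu]


@njit(cache=True)
def _shell_pair_eri(ish, jsh, ksh, lsh, sh_l, sh_np, sh_ps, sh_c,
                    prim_exp, prim_coef, out,
                    Ex1, Ey1, Ez1, Ex2, Ey2, Ez2, comps, R, fbuf):
    """ERI block (ij|kl) over cartesian components of four shells."""
    l1, l2, l3, l4 = sh_l[ish], sh_l[jsh], sh_l[ksh], sh_l[lsh]
    n1 = (l1 + 1) * (l1 + 2) // 2
    n2 = (l2 + 1) * (l2 + 2) // 2
    n3 = (l3 + 1) * (l3 + 2) // 2
    n4 = (l4 + 1) * (l4 + 2) // 2
    c1 = np.zeros((10, 3), dtype=np.int64)
    c2 = np.zeros((10, 3), dtype=np.int64)
    c3 = np.zeros((10, 3), dtype=np.int64)
    c4 = np.zeros((10, 3), dtype=np.int64)
    _cart_powers(l1, c1)
    _cart_powers(l2, c2)
    _cart_powers(l3, c3)
    _cart_powers(l4, c4)
    out[:n1, :n2, :n3, :n4] = 0.0
    ab_x = sh_c[ish, 0] - sh_c[jsh, 0]
    ab_y = sh_c[ish, 1] - sh_c[jsh, 1]
    ab_z = sh_c[ish, 2] - sh_c[jsh, 2]
    cd_x = sh_c[ksh, 0] - sh_c[lsh, 0]
    cd_y = sh_c[ksh, 1] - sh_c[lsh, 1]
    cd_z = sh_c[ksh, 2] - sh_c[lsh, 2]
    for ip in range(sh_np[ish]):
        a = prim_exp[sh_ps[ish] + ip]
        ca = prim_coef[sh_ps[ish] + ip]
        for jp in range(sh_np[jsh]):
            b = prim_exp[sh_ps[jsh] + jp]
            cb = prim_coef[sh_ps[jsh] + jp]
            p = a + b
            px = (a * sh_c[ish, 0] + b * sh_c[jsh, 0]) / p
            py = (a * sh_c[ish, 1] + b * sh_c[jsh, 1]) / p
            pz = (a * sh_c[ish, 2] + b * sh_c[jsh, 2]) / p
            fill_E(l1, l2, a, b, ab_x, Ex1)
            fill_E(l1, l2, a, b, ab_y, Ey1)
            fill_E(l1, l2, a, b, ab_z, Ez1)
            for kp in range(sh_np[ksh]):
                c = prim_exp[sh_ps[ksh] + kp]
                cc_ = prim_coef[sh_ps[ksh] + kp]
                for lp in range(sh_np[lsh]):
                    d = prim_exp[sh_ps[lsh] + lp]
                    cd = prim_coef[sh_ps[lsh] + lp]
                    q = c + d
                    qx = (c * sh_c[ksh, 0] + d * sh_c[lsh, 0]) / q
                    qy = (c * sh_c[ksh, 1] + d * sh_c[lsh, 1]) / q
                    qz = (c * sh_c[ksh, 2] + d * sh_c[lsh, 2]) / q
                    fill_E(l3, l4, c, d, cd_x, Ex2)
                    fill_E(l3, l4, c, d, cd_y, Ey2)
                    fill_E(l3, l4, c, d, cd_z, Ez2)
                    alpha = p * q / (p + q)
                    pref = (ca * cb * cc_ * cd * TWO_PI_POW
                            / (p * q * math.sqrt(p + q)))
                    lsum = l1 + l2 + l3 + l4
                    fill_R(lsum, l1 + l2 + l3 + l4, l1 + l2 + l3 + l4,
                           l1 + l2 + l3 + l4, alpha,
                           px - qx, py - qy, pz - qz, R, fbuf)
                    for i in range(n1):
                        ix, iy, iz = c1[i, 0], c1[i, 1], c1[i, 2]
                        for j in range(n2):
                            jx, jy, jz = c2[j, 0], c2[j, 1], c2[j, 2]
                            for k in range(n3):
                                kx, ky, kz = c3[k, 0], c3[k, 1], c3[k, 2]
                                for m in range(n4):
                                    mx, my, mz = c4[m, 0], c4[m, 1], c4[m, 2]
                                    acc = 0.0
                                    for t in range(ix + jx + 1):
                                        ex1 = Ex1[ix, jx, t]
                                        if ex1 == 0.0:
                                            continue
                                        for u in range(iy + jy + 1):
                                            ey1 = Ey1[iy, jy, u]
                                            if ey1 == 0.0:
                                                continue
                                            for v in range(iz + jz + 1):
                                                ez1 = Ez1[iz, jz, v]
                                                if ez1 == 0.0:
                                                    continue
                                                e1 = ex1 * ey1 * ez1
                                                for tt in range(kx + mx + 1):
                                                    ex2 = Ex2[kx, mx, tt]
                                                    if ex2 == 0.0:
                                                        continue
                                                    for uu in range(ky + my + 1):
                                                        ey2 = Ey2[ky, my, uu]
                                                        if ey2 == 0.0:
                                                            continue
                                                        for vv in range(kz + mz + 1):
                                                            ez2 = Ez2[kz, mz, vv]
                                                            if ez2 == 0.0:
                                                                continue
                                                            sgn = 1.0
                                                            if (tt + uu + vv) % 2 == 1:
                                                                sgn = -1.0
                                                            acc += (e1 * ex2 * ey2 * ez2 * sgn
                                                                    * R[0, t + tt, u + uu, v + vv])
                                    out[i, j, k, m] += pref * acc


@njit(cache=True)
def eri_tensor(sh_l, sh_np, sh_ps, sh_c, sh_ao, prim_exp, prim_coef,
               nao, screen_tol, g):
    """Full in-core chemist-notation ERI tensor with 8-fold symmetry.

    Canonical shell quartets are computed once and mirrored, so the
    permutational symmetry is exact by construction.  ``screen_tol`` is a
    Cauchy-Schwarz prescreen on shell-pair bounds (absolute).
    """
    nsh = sh_l.shape[0]
    Ex1 = np.zeros((4, 6, 10))
    Ey1 = np.zeros((4, 6, 10))
    Ez1 = np.zeros((4, 6, 10))
    Ex2 = np.zeros((4, 6, 10))
    Ey2 = np.zeros((4, 6, 10))
    Ez2 = np.zeros((4, 6, 10))
    comps = np.zeros((10, 3), dtype=np.int64)
    R = np.zeros((10, 10, 10, 10))
    fbuf = np.zeros(12)
    block = np.zeros((10, 10, 10, 10))
    # Schwarz bounds per shell pair
    qbound = np.zeros((nsh, nsh))
    for ish in range(nsh):
        for jsh in range(ish + 1):
            _shell_pair_eri(ish, jsh, ish, jsh, sh_l, sh_np, sh_ps, sh_c,
                            prim_exp, prim_coef, block,
                            Ex1, Ey1, Ez1, Ex2, Ey2, Ez2, comps, R, fbuf)
            n1 = (sh_l[ish] + 1) * (sh_l[ish] + 2) // 2
            n2 = (sh_l[jsh] + 1) * (sh_l[jsh] + 2) // 2
            qmax = 0.0
            for i in range(n1):
                for j in range(n2):
                    v = abs(block[i, j, i, j])
                    if v > qmax:
                        qmax = v
            qbound[ish, jsh] = math.sqrt(qmax)
            qbound[jsh, ish] = qbound[ish, jsh]
    for ish in range(nsh):
        n1 = (sh_l[ish] + 1) * (sh_l[ish] + 2) // 2
        for jsh in range(ish + 1):
            n2 = (sh_l[jsh] + 1) * (sh_l[jsh] + 2) // 2
            for ksh in range(ish + 1):
                n3 = (sh_l[ksh] + 1) * (sh_l[ksh] + 2) // 2
                lmax = ksh if ksh < ish else jsh
                for lsh in range(lmax + 1):
                    if qbound[ish, jsh] * qbound[ksh, lsh] < screen_tol:
                        continue
                    n4 = (sh_l[lsh] + 1) * (sh_l[lsh] + 2) // 2
                    _shell_pair_eri(ish, jsh, ksh, lsh, sh_l, sh_np, sh_ps,
                                    sh_c, prim_exp, prim_coef, block,
                                    Ex1, Ey1, Ez1, Ex2, Ey2, Ez2, comps, R, fbuf)
                    for i in range(n1):
                        mu = sh_ao[ish] + i
                        for j in range(n2):
                            nu = sh_ao[jsh] + j
                            for k in range(n3):
                                lam = sh_ao[ksh] + k
                                for m in range(n4):
                                    sig = sh_ao[lsh] + m
                                    v = block[i, j, k, m]
                                    g[mu, nu, lam, sig] = v
                                    g[nu, mu, lam, sig] = v
                                    g[mu, nu, sig, lam] = v
                                    g[nu, mu, sig, lam] = v
                                    g[lam, sig, mu, nu] = v
                                    g[sig, lam, mu, nu] = v
                                    g[lam, sig, nu, mu] = v
                                    g[sig, lam, nu, mu] = v
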