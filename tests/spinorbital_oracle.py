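"""Independent spin-orbital CCSD/CC2 reference implementation for tests.

This oracle is deliberately formulated differently from the package:
antisymmetrized spin-orbital integrals, explicit t1 amplitudes (no dressed
Hamiltonian), dense 4-index tensors (no Cholesky factorization), and
Jacobian actions by real central finite differences of the residual.  Only
the AO integral layer is shared with the implementation under test.

Residual equations follow the standard spin-orbital CCSD working equations
(Stanton-Gauss-Watts-Bartlett intermediates) with the full Fock matrix, so
Omega = 0 is the amplitude equation and dOmega/dt is the Jacobian whose
eigenvalues are excitation energies.  Singlet eigenstates are obtained by
restricting the Davidson iteration to the spin-adapted (singlet) amplitude
subspace, which is invariant under the Jacobian.
"""

from __future__ import annotations

import numpy as np

from mlccx.solvers import DIISState, davidson_nonsym, diis_step


def spatial_mo_eri(g_ao: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.einsum("abcd,ap,bq,cr,ds->pqrs", g_ao, C, C, C, C, optimize=True)


def spin_orbital_integrals(g_sp: np.ndarray, f_sp: np.ndarray):
    """Antisymmetrized <pq||rs> and spin-orbital Fock from spatial blocks.

    Spin orbitals are ordered 2p (alpha) / 2p+1 (beta).
    """
    n = g_sp.shape[0]
    ns = 2 * n
    g = np.zeros((ns, ns, ns, ns))
    for s1 in (0, 1):
        for s2 in (0, 1):
            # <pq|rs> = (pr|qs) delta(s1,s3) delta(s2,s4)
            g[s1::2, s2::2, s1::2, s2::2] += g_sp.transpose(0, 2, 1, 3)
            g[s1::2, s2::2, s2::2, s1::2] -= g_sp.transpose(0, 2, 3, 1)
    f = np.zeros((ns, ns))
    f[0::2, 0::2] = f_sp
    f[1::2, 1::2] = f_sp
    return g, f


def embed_singlet(t1_sp, t2_sp):
    """Spin-orbital amplitudes of a singlet spin-adapted parametrization."""
    no, nv = t1_sp.shape
    t1 = np.zeros((2 * no, 2 * nv), dtype=t1_sp.dtype)
    t1[0::2, 0::2] = t1_sp
    t1[1::2, 1::2] = t1_sp
    t2 = np.zeros((2 * no, 2 * no, 2 * nv, 2 * nv), dtype=t2_sp.dtype)
    for s1 in (0, 1):
        for s2 in (0, 1):
            t2[s1::2, s2::2, s1::2, s2::2] += t2_sp
            t2[s1::2, s2::2, s2::2, s1::2] -= t2_sp.transpose(0, 1, 3, 2)
    return t1, t2


def extract_rows(r1_so, r2_so):
    """Representative residual rows: (i-alpha, a-alpha) and (a+ i+ b- j-)."""
    return r1_so[0::2, 0::2], r2_so[0::2, 1::2, 0::2, 1::2]


def ccsd_energy(f, g, no, t1, t2):
    o, v = slice(0, no), slice(no, None)
    e = np.einsum("ia,ia->", f[o, v], t1)
    e += 0.25 * np.einsum("ijab,ijab->", g[o, o, v, v], t2)
    e += 0.5 * np.einsum("ijab,ia,jb->", g[o, o, v, v], t1, t1)
    return float(np.real(e))


def ccsd_residual(f, g, no, t1, t2):
    """Spin-orbital CCSD residuals (Omega1[i,a], Omega2[i,j,a,b])."""
    o, v = slice(0, no), slice(no, None)
    tau_t = t2 + 0.5 * (np.einsum("ia,jb->ijab", t1, t1)
                        - np.einsum("ib,ja->ijab", t1, t1))
    tau = t2 + (np.einsum("ia,jb->ijab", t1, t1)
                - np.einsum("ib,ja->ijab", t1, t1))
    Fae = (f[v, v] - 0.5 * np.einsum("me,ma->ae", f[o, v], t1)
           + np.einsum("mf,mafe->ae", t1, g[o, v, v, v])
           - 0.5 * np.einsum("mnaf,mnef->ae", tau_t, g[o, o, v, v]))
    Fmi = (f[o, o] + 0.5 * np.einsum("ie,me->mi", t1, f[o, v])
           + np.einsum("ne,mnie->mi", t1, g[o, o, o, v])
           + 0.5 * np.einsum("inef,mnef->mi", tau_t, g[o, o, v, v]))
    Fme = f[o, v] + np.einsum("nf,mnef->me", t1, g[o, o, v, v])
    Wmnij = (g[o, o, o, o]
             + np.einsum("je,mnie->mnij", t1, g[o, o, o, v])
             - np.einsum("ie,mnje->mnij", t1, g[o, o, o, v])
             + 0.25 * np.einsum("ijef,mnef->mnij", tau, g[o, o, v, v]))
    Wabef = (g[v, v, v, v]
             - np.einsum("mb,amef->abef", t1, g[v, o, v, v])
             + np.einsum("ma,bmef->abef", t1, g[v, o, v, v])
             + 0.25 * np.einsum("mnab,mnef->abef", tau, g[o, o, v, v]))
    Wmbej = (g[o, v, v, o]
             + np.einsum("jf,mbef->mbej", t1, g[o, v, v, v])
             - np.einsum("nb,mnej->mbej", t1, g[o, o, v, o])
             - np.einsum("jnfb,mnef->mbej",
                         0.5 * t2 + np.einsum("jf,nb->jnfb", t1, t1),
                         g[o, o, v, v]))
    r1 = (f[o, v] + np.einsum("ie,ae->ia", t1, Fae)
          - np.einsum("ma,mi->ia", t1, Fmi)
          + np.einsum("imae,me->ia", t2, Fme)
          - np.einsum("nf,naif->ia", t1, g[o, v, o, v])
          - 0.5 * np.einsum("imef,maef->ia", t2, g[o, v, v, v])
          - 0.5 * np.einsum("mnae,nmei->ia", t2, g[o, o, v, o]))
    tmp_ae = Fae - 0.5 * np.einsum("mb,me->be", t1, Fme)
    tmp_mi = Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme)
    r2 = g[o, o, v, v].copy()
    x = np.einsum("ijae,be->ijab", t2, tmp_ae)
    r2 += x - x.transpose(0, 1, 3, 2)
    x = np.einsum("imab,mj->ijab", t2, tmp_mi)
    r2 -= x - x.transpose(1, 0, 2, 3)
    r2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij)
    r2 += 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef)
    x = (np.einsum("imae,mbej->ijab", t2, Wmbej)
         - np.einsum("ie,ma,mbej->ijab", t1, t1, g[o, v, v, o]))
    x = x - x.transpose(0, 1, 3, 2)
    r2 += x - x.transpose(1, 0, 2, 3)
    x = np.einsum("ie,abej->ijab", t1, g[v, v, v, o])
    r2 += x - x.transpose(1, 0, 2, 3)
    x = np.einsum("ma,mbij->ijab", t1, g[o, v, o, o])
    r2 -= x - x.transpose(0, 1, 3, 2)
    return r1, r2


def cc2_residual(f, g, no, t1, t2):
    """Spin-orbital CC2: full singles equation; doubles = driver + [F, T2].

    The doubles driver <mu2|e^{-T1} H e^{T1}|HF> equals the CCSD doubles
    residual at t2 = 0; the Fock commutator adds the orbital-energy
    denominator (f is diagonal in the canonical basis).
    """
    r1, _ = ccsd_residual(f, g, no, t1, t2)
    _, r2_drv = ccsd_residual(f, g, no, t1, np.zeros_like(t2))
    eps = np.diag(f)
    eo, ev = eps[:no], eps[no:]
    D = (ev[None, None, :, None] + ev[None, None, None, :]
         - eo[:, None, None, None] - eo[None, :, None, None])
    return r1, r2_drv + D * t2


def solve_ground(f, g, no, residual, tol=1e-8, max_iter=200):
    """Quasi-Newton + DIIS solution of the spin-orbital amplitude equations."""
    ns = f.shape[0]
    nv = ns - no
    eps = np.diag(f)
    d1 = eps[no:][None, :] - eps[:no][:, None]
    d2 = (eps[no:][None, None, :, None] + eps[no:][None, None, None, :]
          - eps[:no][:, None, None, None] - eps[:no][None, :, None, None])
    t1 = np.zeros((no, nv))
    t2 = np.zeros((no, no, nv, nv))
    diis = DIISState(max_size=8)
    for it in range(max_iter):
        r1, r2 = residual(f, g, no, t1, t2)
        rn = np.sqrt(np.sum(r1 ** 2) + np.sum(r2 ** 2))
        if rn <= tol:
            return t1, t2, it
        s1, s2 = r1 / d1, r2 / d2
        x = diis_step(
            diis,
            np.concatenate([(t1 - s1).ravel(), (t2 - s2).ravel()]),
            np.concatenate([s1.ravel(), s2.ravel()]),
        )
        t1 = x[: no * nv].reshape(no, nv)
        t2 = x[no * nv:].reshape(no, no, nv, nv)
        # re-enforce exact antisymmetry lost in extrapolation round-off
        t2 = 0.25 * (t2 - t2.transpose(1, 0, 2, 3)
                     - t2.transpose(0, 1, 3, 2) + t2.transpose(1, 0, 3, 2))
    raise RuntimeError(f"oracle ground state not converged ({rn:.2e})")


class SingletJacobianFD:
    """Finite-difference Jacobian action restricted to the singlet subspace.

    Coordinates are (t1[i,a]; t2 over unique pairs ai >= bj) exactly as in
    the package; sigma(x) = [Omega(T + eps E x) - Omega(T - eps E x)]/2eps
    with rows read at the representative spin components.
    """

    def __init__(self, f, g, no_sp, residual, t1_sp, t2_sp, eps_fd=1e-5):
        self.f, self.g = f, g
        self.no_sp = no_sp
        self.residual = residual
        self.t1_sp, self.t2_sp = t1_sp, t2_sp
        self.eps_fd = eps_fd
        no, nv = t1_sp.shape
        self.no, self.nv = no, nv
        self.P = no * nv
        self.tril = np.tril_indices(self.P)
        self.size = no * nv + self.tril[0].size

    def pack(self, r1_sp, r2_sp):
        out = np.empty(self.size)
        out[: self.P] = r1_sp.ravel()
        M = r2_sp.transpose(0, 2, 1, 3).reshape(self.P, self.P)
        out[self.P:] = M[self.tril]
        return out

    def unpack(self, x):
        t1 = x[: self.P].reshape(self.no, self.nv)
        M = np.zeros((self.P, self.P))
        M[self.tril] = x[self.P:]
        M.T[self.tril] = x[self.P:]
        t2 = M.reshape(self.no, self.nv, self.no, self.nv).transpose(0, 2, 1, 3)
        return t1, t2

    def omega_rows(self, t1_sp, t2_sp):
        no2 = 2 * self.no
        t1_so, t2_so = embed_singlet(t1_sp, t2_sp)
        r1_so, r2_so = self.residual(self.f, self.g, no2, t1_so, t2_so)
        return self.pack(*extract_rows(r1_so, r2_so))

    def __call__(self, x):
        d1, d2 = self.unpack(x)
        e = self.eps_fd
        plus = self.omega_rows(self.t1_sp + e * d1, self.t2_sp + e * d2)
        minus = self.omega_rows(self.t1_sp - e * d1, self.t2_sp - e * d2)
        return (plus - minus) / (2.0 * e)

    def diagonal(self):
        eps = np.diag(self.f)
        eo = eps[: 2 * self.no : 2]
        ev = eps[2 * self.no :: 2]
        d1 = (ev[None, :] - eo[:, None]).ravel()
        dp = d1
        d2 = dp[:, None] + dp[None, :]
        return np.concatenate([d1, d2[self.tril]])


def extract_singlet_spatial(t1_so, t2_so):
    """Spatial spin-adapted amplitudes from singlet spin-orbital ones."""
    return t1_so[0::2, 0::2].copy(), t2_so[0::2, 1::2, 0::2, 1::2].copy()


def oracle_excitations(f, g, no_so, residual, t1_so, t2_so, n_states,
                       tol=1e-6, seed=3):
    """Lowest singlet excitation energies from the FD Jacobian."""
    t1_sp, t2_sp = extract_singlet_spatial(t1_so, t2_so)
    jac = SingletJacobianFD(f, g, no_so // 2, residual, t1_sp, t2_sp)
    res = davidson_nonsym(jac, jac.diagonal(), n_states, tol=tol, seed=seed)
    return res.values
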