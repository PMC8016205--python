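"""Shared closed-shell coupled-cluster machinery in the X1-dressed basis.

The cluster operator is X1 (unrestricted singles) plus a doubles operator
restricted to the active orbital space.  All residuals are formulated in
terms of the X1-transformed (dressed) Cholesky vectors

    L~^J = (I - x1) L^J (I + x1),

where x1 carries the singles amplitudes in its virtual-occupied block.  The
dressed two-electron integrals g~_pqrs = sum_J L~^J_pq L~^J_rs keep the
pair-exchange symmetry (pq|rs) = (rs|pq) but lose (pq) <-> (qp); the first
index of each pair is the creation (bra) index.

Residual rows are normalized so that they equal the corresponding
spin-orbital residual components at the mapped amplitudes
(t^so_{a+ i+ b- j-} = t2[i,j,a,b]); with amplitudes parametrized over the
unique singlet pairs ai >= bj, the Jacobian eigenvalues in these
coordinates are exactly the singlet excitation energies.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cholesky import CholeskyERI
from .orbitals import OrbitalPartition
from .scf import SCFReference
from .solvers import DIISState, davidson_nonsym, diis_step

HARTREE_TO_EV = 27.211386


@dataclass
class CCAmplitudes:
    """Unrestricted singles t1[i,a]; active-restricted doubles t2[i,j,a,b]."""

    t1: np.ndarray
    t2: np.ndarray  # (n_oa, n_oa, n_va, n_va), symmetric under (ia)<->(jb)

    def copy(self) -> "CCAmplitudes":
        return CCAmplitudes(self.t1.copy(), self.t2.copy())


@dataclass
class CCSystem:
    """Partitioned-basis data consumed by the CC residual code.

    ``L``: MO Cholesky factors in the (semicanonical) partition basis.
    ``F0``: reference Fock matrix in the same basis (includes any frozen
    Fock contribution).  ``h``: effective one-electron matrix defined as
    F0 minus the Cholesky-factor mean field, so that the dressed Fock at
    x1 = 0 reproduces F0 exactly (Brillouin holds to machine precision
    regardless of the decomposition threshold).
    """

    L: np.ndarray
    F0: np.ndarray
    h: np.ndarray
    eps: np.ndarray
    n_occ: int
    n_occ_active: int
    n_virt_active: int
    e_scf: float

    @property
    def n_mo(self) -> int:
        return self.F0.shape[0]

    @property
    def n_virt(self) -> int:
        return self.n_mo - self.n_occ

    @property
    def oa(self) -> slice:
        """Active occupied orbitals within the occupied block."""
        return slice(self.n_occ - self.n_occ_active, self.n_occ)

    @property
    def va(self) -> slice:
        """Active virtual orbitals within the virtual block."""
        return slice(0, self.n_virt_active)

    def zero_amplitudes(self) -> CCAmplitudes:
        noa, nva = self.n_occ_active, self.n_virt_active
        return CCAmplitudes(
            np.zeros((self.n_occ, self.n_virt)),
            np.zeros((noa, noa, nva, nva)),
        )


def make_cc_system(
    reference: SCFReference,
    partition: OrbitalPartition,
    cderi: CholeskyERI,
) -> CCSystem:
    """Assemble the CC-layer view of a partitioned, Cholesky-factorized system.

    ``cderi`` must be expressed in the partition basis (occ block first).
    The partition must be semicanonical so the perturbative doubles can be
    solved analytically.
    """
    if not partition.semicanonical:
        raise ValueError("partition must be semicanonicalized first")
    C = partition.C
    n_occ = partition.n_occ
    F0 = C.T @ reference.F_ao @ C
    F0 = 0.5 * (F0 + F0.T)
    L = cderi.L
    jk0 = _mean_field(L, n_occ)
    h = F0 - jk0
    return CCSystem(
        L=L, F0=F0, h=h, eps=np.diag(F0).copy(), n_occ=n_occ,
        n_occ_active=partition.n_occ_active,
        n_virt_active=partition.n_virt_active,
        e_scf=reference.energy,
    )


def _mean_field(L: np.ndarray, n_occ: int) -> np.ndarray:
    """Closed-shell Coulomb-exchange mean field of the factorized integrals."""
    tr = np.einsum("jkk->j", L[:, :n_occ, :n_occ])
    J = np.einsum("j,jpq->pq", tr, L, optimize=True)
    K = np.einsum("jpk,jkq->pq", L[:, :, :n_occ], L[:, :n_occ, :], optimize=True)
    return 2.0 * J - K


def x1_transform_cholesky(ccsys: CCSystem, t1: np.ndarray):
    """Dressed Cholesky vectors, one-electron matrix and Fock matrix.

    Dressing twice with t1 and -t1 is the identity (the x1 block is
    nilpotent).  Returns (L~, h~, F~); F~ rows are creation-side indices,
    so F~ is not symmetric for nonzero t1.
    """
    n, no = ccsys.n_mo, ccsys.n_occ
    dtype = np.result_type(ccsys.L.dtype, t1.dtype)
    lam_l = np.eye(n, dtype=dtype)
    lam_l[no:, :no] -= t1.T
    lam_r = np.eye(n, dtype=dtype)
    lam_r[no:, :no] += t1.T
    Ld = np.einsum("pa,jab,bq->jpq", lam_l, ccsys.L, lam_r, optimize=True)
    hd = lam_l @ ccsys.h @ lam_r
    Fd = hd + _mean_field(Ld, no)
    return Ld, hd, Fd


def reference_energy_shift(ccsys: CCSystem, Ld, hd) -> np.ndarray:
    """<HF| e^{-X1} H e^{X1} |HF> minus <HF|H|HF> (both with factorized g)."""
    no = ccsys.n_occ

    def eref(Lx, hx):
        tr = np.einsum("jkk->j", Lx[:, :no, :no])
        coul = np.dot(tr, tr)
        exch = np.einsum("jik,jki->", Lx[:, :no, :no], Lx[:, :no, :no])
        return 2.0 * np.trace(hx[:no, :no]) + 2.0 * coul - exch

    return eref(Ld, hd) - eref(ccsys.L, ccsys.h)


def _u(t2: np.ndarray) -> np.ndarray:
    """Spin-summed combination 2 t2[i,j,a,b] - t2[i,j,b,a]."""
    return 2.0 * t2 - t2.transpose(0, 1, 3, 2)


def omega(ccsys: CCSystem, amps: CCAmplitudes, method: str):
    """Projected residual (Omega1[i,a], Omega2[i,j,a,b]) for mlcc2/mlccsd.

    The singles projection is unrestricted; the doubles projection is
    restricted to the active quadruples.  ``method`` selects the doubles
    equation: 'cc2' keeps only the bare-Fock commutator with the doubles,
    'ccsd' keeps the full set of dressed CCSD contractions.
    """
    no, nv = ccsys.n_occ, ccsys.n_virt
    oa, va = ccsys.oa, ccsys.va
    noa, nva = ccsys.n_occ_active, ccsys.n_virt_active
    t1, t2 = amps.t1, amps.t2
    Ld, hd, Fd = x1_transform_cholesky(ccsys, t1)
    u = _u(t2)

    Loo = Ld[:, :no, :no]
    Lov = Ld[:, :no, no:]
    Lvo = Ld[:, no:, :no]
    Lvv = Ld[:, no:, no:]

    # ---- singles residual: F~_ai + linear T2 terms (shared CCS machinery)
    om1 = np.array(Fd[no:, :no].T, dtype=Fd.dtype)  # [i,a]
    if noa and nva:
        # S1: sum_me u[i,m,a,e] F~[m,e]
        om1[oa, va] += np.einsum(
            "imae,me->ia", u, Fd[oa, no:][:, va], optimize=True
        )
        # S2: sum_mef u[i,m,e,f] g~[m,f,a,e]  (g~ = L~ov . L~vv)
        A = np.einsum("imef,jmf->jie", u, Lov[:, oa, :][:, :, va], optimize=True)
        om1[oa, :] += np.einsum("jie,jae->ia", A, Lvv[:, :, va], optimize=True)
        # S3: -sum_mne u[m,n,a,e] g~[n,e,m,i]  (g~ = L~ov . L~oo)
        B = np.einsum("mnae,jne->jma", u, Lov[:, oa, :][:, :, va], optimize=True)
        om1[:, va] -= np.einsum("jma,jmi->ia", B, Loo[:, oa, :], optimize=True)

    # ---- doubles residual over active quadruples
    if noa == 0 or nva == 0:
        om2 = np.zeros((noa, noa, nva, nva), dtype=om1.dtype)
        return om1, om2

    Lvo_a = Lvo[:, va, :][:, :, oa]  # (J, va, oa)
    # driving term g~[a,i,b,j] (creation a,b)
    om2 = np.einsum("jai,jbk->iakb", Lvo_a, Lvo_a, optimize=True)
    om2 = om2.transpose(0, 2, 1, 3).copy()  # -> [i,j,a,b]

    if method == "cc2":
        Fvv = ccsys.F0[no:, no:][va, va]
        Foo = ccsys.F0[:no, :no][oa, oa]
        om2 += np.einsum("ijae,be->ijab", t2, Fvv, optimize=True)
        om2 += np.einsum("ijeb,ae->ijab", t2, Fvv, optimize=True)
        om2 -= np.einsum("imab,mj->ijab", t2, Foo, optimize=True)
        om2 -= np.einsum("mjab,mi->ijab", t2, Foo, optimize=True)
        return om1, om2
    if method != "ccsd":
        raise ValueError(f"unknown method {method!r}")

    Loo_a = Loo[:, oa, :][:, :, oa]
    Lov_a = Lov[:, oa, :][:, :, va]
    Lvv_a = Lvv[:, va, :][:, :, va]
    # active-block dressed integrals
    g_ovov = np.einsum("jme,jnf->menf", Lov_a, Lov_a, optimize=True)
    Lg = 2.0 * g_ovov - g_ovov.transpose(0, 3, 2, 1)
    g_oooo = np.einsum("jmi,jnk->mink", Loo_a, Loo_a, optimize=True)
    g_vvvv = np.einsum("jae,jbf->aebf", Lvv_a, Lvv_a, optimize=True)
    g_ovvo = np.einsum("jme,jbk->mebk", Lov_a, Lvo_a, optimize=True)
    g_oovv = np.einsum("jmi,jbe->mibe", Loo_a, Lvv_a, optimize=True)

    # B/C terms with their quadratic mean-field corrections
    Gvv = Fd[no:, no:][va, va] - np.einsum("mnbf,menf->be", t2, Lg, optimize=True)
    Goo = Fd[:no, :no][oa, oa] + np.einsum("jnef,menf->mj", t2, Lg, optimize=True)
    om2 += np.einsum("ijae,be->ijab", t2, Gvv, optimize=True)
    om2 += np.einsum("ijeb,ae->ijab", t2, Gvv, optimize=True)
    om2 -= np.einsum("imab,mj->ijab", t2, Goo, optimize=True)
    om2 -= np.einsum("mjab,mi->ijab", t2, Goo, optimize=True)
    # oooo ladder (with the quadratic "B-term" folded in) and vvvv ladder
    W = g_oooo + np.einsum("ijef,menf->minj", t2, g_ovov, optimize=True)
    om2 += np.einsum("mnab,minj->ijab", t2, W, optimize=True)
    om2 += np.einsum("ijef,aebf->ijab", t2, g_vvvv, optimize=True)
    # ring terms, linear
    ring = (
        np.einsum("imae,mebj->ijab", u, g_ovvo, optimize=True)
        - np.einsum("imae,mjbe->ijab", t2, g_oovv, optimize=True)
        - np.einsum("mjae,mibe->ijab", t2, g_oovv, optimize=True)
    )
    om2 += ring + ring.transpose(1, 0, 3, 2)
    # ring terms, quadratic: -X1 + X2 from the spin summation of
    # -1/2 P(ij) P(ab) t_imae t_jnfb <mn||ef> at mixed-spin externals
    tm = t2 - t2.transpose(0, 1, 3, 2)  # same-spin combination
    e_ = np.einsum
    x1 = (
        -e_("imae,jnbf,menf->ijab", tm, t2, g_ovov, optimize=True)
        + e_("imae,jnbf,mfne->ijab", tm, t2, g_ovov, optimize=True)
        + e_("imae,jnfb,menf->ijab", tm, tm, g_ovov, optimize=True)
        - e_("imae,jnbf,menf->ijab", t2, t2, g_ovov, optimize=True)
        + e_("imae,jnfb,menf->ijab", t2, tm, g_ovov, optimize=True)
        - e_("imae,jnfb,mfne->ijab", t2, tm, g_ovov, optimize=True)
    )
    x2 = e_("jmea,infb,mfne->ijab", t2, t2, g_ovov, optimize=True)
    om2 += -x1 + x2
    return om1, om2


def correlation_energy(ccsys: CCSystem, amps: CCAmplitudes) -> float:
    """MLCC correlation energy from the dressed reference and active doubles."""
    Ld, hd, _ = x1_transform_cholesky(ccsys, amps.t1)
    e1 = reference_energy_shift(ccsys, Ld, hd)
    if ccsys.n_occ_active and ccsys.n_virt_active:
        Lov_a = Ld[:, :ccsys.n_occ, ccsys.n_occ:][:, ccsys.oa, :][:, :, ccsys.va]
        g_ovov = np.einsum("jia,jkb->iakb", Lov_a, Lov_a, optimize=True)
        e2 = np.einsum(
            "ijab,iajb->", _u(amps.t2), g_ovov, optimize=True
        )
    else:
        e2 = 0.0
    return float(np.real(e1 + e2))


# ---- packing over unique singlet pairs -----------------------------------


class PairPacking:
    """Flat real parametrization (t1 all; t2 over unique active pairs)."""

    def __init__(self, ccsys: CCSystem):
        self.no, self.nv = ccsys.n_occ, ccsys.n_virt
        self.noa, self.nva = ccsys.n_occ_active, ccsys.n_virt_active
        self.n1 = self.no * self.nv
        P = self.noa * self.nva
        self.P = P
        self.tril = np.tril_indices(P)
        self.n2 = self.tril[0].size
        self.size = self.n1 + self.n2

    def pack(self, amps: CCAmplitudes) -> np.ndarray:
        out = np.empty(self.size, dtype=amps.t1.dtype)
        out[: self.n1] = amps.t1.ravel()
        if self.n2:
            M = amps.t2.transpose(0, 2, 1, 3).reshape(self.P, self.P)
            out[self.n1:] = M[self.tril]
        return out

    def unpack(self, x: np.ndarray) -> CCAmplitudes:
        t1 = x[: self.n1].reshape(self.no, self.nv)
        M = np.zeros((self.P, self.P), dtype=x.dtype)
        if self.n2:
            M[self.tril] = x[self.n1:]
            M.T[self.tril] = x[self.n1:]
        t2 = M.reshape(self.noa, self.nva, self.noa, self.nva).transpose(0, 2, 1, 3)
        return CCAmplitudes(t1=np.array(t1), t2=np.array(t2))

    def pack_residual(self, om1: np.ndarray, om2: np.ndarray) -> np.ndarray:
        out = np.empty(self.size, dtype=om1.dtype)
        out[: self.n1] = om1.ravel()
        if self.n2:
            M = om2.transpose(0, 2, 1, 3).reshape(self.P, self.P)
            out[self.n1:] = M[self.tril]
        return out

    def diagonal_estimate(self, ccsys: CCSystem) -> np.ndarray:
        """Orbital-energy-difference diagonal for preconditioning."""
        no = ccsys.n_occ
        eo, ev = ccsys.eps[:no], ccsys.eps[no:]
        d1 = (ev[None, :] - eo[:, None]).ravel()
        if self.n2 == 0:
            return d1
        eoa, eva = eo[ccsys.oa], ev[ccsys.va]
        dp = (eva[None, :] - eoa[:, None]).ravel()
        d2 = dp[:, None] + dp[None, :]
        return np.concatenate([d1, d2[self.tril]])


def residual_function(ccsys: CCSystem, method: str, packing: PairPacking):
    def f(x: np.ndarray) -> np.ndarray:
        amps = packing.unpack(x)
        om1, om2 = omega(ccsys, amps, method)
        return packing.pack_residual(om1, om2)

    return f


def jacobian_apply(
    ccsys: CCSystem,
    amps: CCAmplitudes,
    trial: np.ndarray,
    method: str,
    packing: PairPacking | None = None,
) -> np.ndarray:
    """Matrix-free Jacobian action A @ r at the given amplitudes.

    Evaluated as the complex-step directional derivative of the residual,
    Im Omega(t + i h r)/h with h = 1e-100: exact to machine precision for
    the polynomial residual, and by construction identical to dOmega/dt.
    """
    if packing is None:
        packing = PairPacking(ccsys)
    f = residual_function(ccsys, method, packing)
    x0 = packing.pack(amps).astype(complex)
    h = 1e-100
    return np.imag(f(x0 + 1j * h * trial)) / h


# ---- ground-state and excited-state solvers ------------------------------


class CCConvergenceError(RuntimeError):
    def __init__(self, msg: str, history: list[float]):
        super().__init__(msg)
        self.history = history


def solve_s2(ccsys: CCSystem, t1: np.ndarray) -> np.ndarray:
    """Analytic perturbative doubles in the semicanonical basis.

    t2[i,j,a,b] = -g~[a,i,b,j] / (eps_a + eps_b - eps_i - eps_j) over the
    active quadruples; requires diagonal active-active Fock blocks.
    """
    noa, nva = ccsys.n_occ_active, ccsys.n_virt_active
    if noa == 0 or nva == 0:
        return np.zeros((noa, noa, nva, nva))
    no = ccsys.n_occ
    Fvv = ccsys.F0[no:, no:][ccsys.va, ccsys.va]
    Foo = ccsys.F0[:no, :no][ccsys.oa, ccsys.oa]
    if (np.max(np.abs(Fvv - np.diag(np.diag(Fvv)))) > 1e-8
            or np.max(np.abs(Foo - np.diag(np.diag(Foo)))) > 1e-8):
        raise ValueError("active-active Fock blocks are not diagonal "
                         "(semicanonicalize the partition first)")
    Ld, _, _ = x1_transform_cholesky(ccsys, t1)
    Lvo_a = Ld[:, no:, :no][:, ccsys.va, :][:, :, ccsys.oa]
    g = np.einsum("jai,jbk->iakb", Lvo_a, Lvo_a, optimize=True).transpose(0, 2, 1, 3)
    eo, ev = np.diag(Foo), np.diag(Fvv)
    denom = (ev[None, None, :, None] + ev[None, None, None, :]
             - eo[:, None, None, None] - eo[None, :, None, None])
    if np.min(np.abs(denom)) < 1e-10:
        raise ZeroDivisionError(
            "vanishing semicanonical doubles denominator; degenerate "
            "active orbital energies require explicit handling"
        )
    return -np.real(g) / denom


def ground_state(
    ccsys: CCSystem,
    method: str,
    tol: float = 1e-6,
    max_iter: int = 100,
    diis_size: int = 8,
):
    """DIIS-accelerated quasi-Newton solution of the ground-state equations.

    Returns (total energy, correlation energy, amplitudes, iteration info).
    For mlcc2 the doubles are eliminated analytically every iteration; for
    mlccsd singles and doubles are relaxed jointly.
    """
    packing = PairPacking(ccsys)
    no = ccsys.n_occ
    eo, ev = ccsys.eps[:no], ccsys.eps[no:]
    d1 = ev[None, :] - eo[:, None]
    amps = ccsys.zero_amplitudes()
    diis = DIISState(max_size=diis_size)
    history: list[float] = []
    for it in range(max_iter):
        if method == "cc2":
            amps.t2 = solve_s2(ccsys, amps.t1)
        om1, om2 = omega(ccsys, amps, method)
        resid = packing.pack_residual(om1, om2)
        rnorm = float(np.linalg.norm(resid))
        history.append(rnorm)
        if rnorm <= tol:
            ecorr = correlation_energy(ccsys, amps)
            return ccsys.e_scf + ecorr, ecorr, amps, {
                "iterations": it, "residual_norms": history,
            }
        if method == "cc2":
            t1_new = amps.t1 - om1 / d1
            x = diis_step(diis, t1_new.ravel(), (om1 / d1).ravel())
            amps.t1 = x.reshape(amps.t1.shape)
        else:
            x = packing.pack(amps)
            step = resid / packing.diagonal_estimate(ccsys)
            x_new = x - step
            x = diis_step(diis, x_new, step)
            amps = packing.unpack(x)
    raise CCConvergenceError(
        f"{method} ground state not converged to {tol:g} in {max_iter} "
        f"iterations (|Omega| history tail {history[-3:]})", history
    )


def excited_states(
    ccsys: CCSystem,
    amps: CCAmplitudes,
    method: str,
    n_states: int,
    tol: float = 1e-4,
    seed: int = 0,
    max_iter: int = 300,
):
    """Lowest right eigenpairs of the MLCC Jacobian via non-symmetric Davidson.

    Returns a list of (omega, packed eigenvector) sorted ascending.
    """
    packing = PairPacking(ccsys)
    f = residual_function(ccsys, method, packing)
    x0 = packing.pack(amps).astype(complex)
    h = 1e-100

    def apply_A(r: np.ndarray) -> np.ndarray:
        return np.imag(f(x0 + 1j * h * r)) / h

    diag = packing.diagonal_estimate(ccsys)
    res = davidson_nonsym(
        apply_A, diag, n_states, tol=tol, seed=seed, max_iter=max_iter
    )
    return [
        (float(res.values[k]), res.vectors[:, k]) for k in range(n_states)
    ]
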