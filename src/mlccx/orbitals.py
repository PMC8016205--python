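"""Active orbital-space construction and selection.

Two families of partitioned orbitals are provided:

* correlated natural transition orbitals (CNTOs) built from CCS excitation
  vectors plus perturbative approximate doubles, ranked by eigenvalue;
* localized orbitals for spatial regions: restricted pivoted Cholesky
  decomposition of the occupied density, and projected atomic orbitals
  (PAOs) for the virtual space.

All partitions are S-orthonormal and complete, and can be transformed to the
semicanonical basis (active-active and inactive-inactive occupied/virtual
Fock blocks diagonal) required by the perturbative doubles solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg as sla

from .cholesky import CholeskyERI
from .scf import SCFReference
from .solvers import davidson_nonsym


@dataclass
class OrbitalPartition:
    """Retained MOs ordered (inactive-occ | active-occ | active-virt | inactive-virt)."""

    C: np.ndarray  # AO x n_mo retained (excludes frozen orbitals)
    n_occ_inactive: int
    n_occ_active: int
    n_virt_active: int
    n_virt_inactive: int
    semicanonical: bool = False
    provenance: str = "canonical"
    eps: np.ndarray | None = None

    @property
    def n_occ(self) -> int:
        return self.n_occ_inactive + self.n_occ_active

    @property
    def n_virt(self) -> int:
        return self.n_virt_active + self.n_virt_inactive

    @property
    def n_mo(self) -> int:
        return self.n_occ + self.n_virt

    @property
    def occ_active_slice(self) -> slice:
        return slice(self.n_occ_inactive, self.n_occ)

    @property
    def virt_active_slice(self) -> slice:
        return slice(self.n_occ, self.n_occ + self.n_virt_active)

    def block_slices(self) -> list[slice]:
        no_i, no_a = self.n_occ_inactive, self.n_occ_active
        nv_a, nv_i = self.n_virt_active, self.n_virt_inactive
        edges = np.cumsum([0, no_i, no_a, nv_a, nv_i])
        return [slice(int(a), int(b)) for a, b in zip(edges[:-1], edges[1:])]


@dataclass
class CNTODensities:
    """Occupied/virtual CNTO matrices M and N with their source vectors."""

    M: np.ndarray  # (N_o, N_o)
    N: np.ndarray  # (N_v, N_v)
    states: list = field(default_factory=list)  # [(omega, R1, R2), ...]


def s_orthonormalize(S: np.ndarray, X: np.ndarray, lindep_tol: float = 1e-8,
                     n_keep: int | None = None) -> np.ndarray:
    """Canonical (Lowdin) orthonormalization of columns X in the S metric."""
    if X.shape[1] == 0:
        return X
    O = X.T @ S @ X
    O = 0.5 * (O + O.T)
    lam, V = sla.eigh(O)
    if n_keep is not None:
        keep = np.argsort(lam)[::-1][:n_keep]
        keep = keep[lam[keep] > lindep_tol]
    else:
        keep = np.nonzero(lam > lindep_tol)[0]
    lam, V = lam[keep], V[:, keep]
    order = np.argsort(lam)[::-1]
    lam, V = lam[order], V[:, order]
    return X @ V / np.sqrt(lam)[None, :]


def cholesky_occupied_orbitals(
    D: np.ndarray,
    S: np.ndarray,
    active_aos,
    C_occ: np.ndarray,
    pivot_tol: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Localized occupied orbitals by restricted pivoted Cholesky of D.

    The pivots are restricted to AOs centered on active atoms; the threshold
    applies to the updated density diagonal.  Returns (active, inactive)
    occupied coefficient blocks, jointly spanning the occupied space and
    S-orthonormal.
    """
    active_aos = sorted(set(int(a) for a in active_aos))
    n_occ = C_occ.shape[1]
    if not active_aos:
        return np.zeros((D.shape[0], 0)), C_occ.copy()
    R = D.copy()
    vecs = []
    for _ in range(n_occ):
        diag = np.diag(R)[active_aos]
        k = int(np.argmax(diag))
        if diag[k] <= pivot_tol:
            break
        piv = active_aos[k]
        ell = R[:, piv] / np.sqrt(R[piv, piv])
        vecs.append(ell)
        R = R - np.outer(ell, ell)
    if len(vecs) == n_occ and np.max(np.diag(R)) > pivot_tol:
        raise RuntimeError(
            f"pivot threshold {pivot_tol:g} exhausted the occupied rank"
        )
    if not vecs:
        return np.zeros((D.shape[0], 0)), C_occ.copy()
    C_act = s_orthonormalize(S, np.column_stack(vecs), lindep_tol=1e-10)
    # inactive occupieds: occupied span with the active part projected out
    proj = C_act @ (C_act.T @ S @ C_occ)
    C_in = s_orthonormalize(S, C_occ - proj, lindep_tol=1e-8,
                            n_keep=n_occ - C_act.shape[1])
    return C_act, C_in


def construct_paos(
    D: np.ndarray,
    S: np.ndarray,
    active_aos,
    lindep_tol: float = 1e-6,
    C_virt_span: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Active/inactive virtual orbitals from projected atomic orbitals.

    The occupied space is projected out of the AOs on active atoms,
    C^PAO = (I - D S)'; the surviving span (above ``lindep_tol`` in the
    canonical orthonormalization) forms the active virtuals.  Inactive
    virtuals additionally have the active virtuals projected out.  If
    ``C_virt_span`` is given, the construction is confined to that virtual
    span (used when partitioning an already-reduced space).
    """
    active_aos = sorted(set(int(a) for a in active_aos))
    if not active_aos:
        raise ValueError("active_aos must be non-empty for PAO construction")
    n_ao = D.shape[0]
    if C_virt_span is None:
        Pv = np.eye(n_ao) - D @ S  # projector onto the virtual space (S-metric)
        n_virt_total = n_ao - int(round(np.trace(D @ S)))
    else:
        Pv = C_virt_span @ (C_virt_span.T @ S)
        n_virt_total = C_virt_span.shape[1]
    C_pao = Pv[:, active_aos]
    C_act = s_orthonormalize(S, C_pao, lindep_tol=lindep_tol)
    if C_act.shape[1] == 0:
        raise RuntimeError(
            "all projected AOs fell below the linear-dependence threshold"
        )
    n_va = C_act.shape[1]
    # inactive virtuals: project occupieds and active virtuals out of all AOs
    X = Pv - C_act @ (C_act.T @ S @ Pv)
    C_in = s_orthonormalize(S, X, lindep_tol=1e-8, n_keep=n_virt_total - n_va)
    return C_act, C_in


def canonicalize_blocks(F_ao: np.ndarray, C: np.ndarray, blocks: list[slice]):
    """Diagonalize F within each orbital block; returns (C', eps)."""
    C = C.copy()
    eps = np.zeros(C.shape[1])
    for sl in blocks:
        if sl.stop - sl.start == 0:
            continue
        Fb = C[:, sl].T @ F_ao @ C[:, sl]
        Fb = 0.5 * (Fb + Fb.T)
        e, U = sla.eigh(Fb)
        C[:, sl] = C[:, sl] @ U
        eps[sl] = e
    return C, eps


def semicanonicalize(F_ao: np.ndarray, partition: OrbitalPartition) -> OrbitalPartition:
    """Block-rotate so active-active and inactive-inactive Fock blocks are diagonal.

    Occupied/virtual spans are unchanged (rotations act within blocks only).
    """
    C, eps = canonicalize_blocks(F_ao, partition.C, partition.block_slices())
    return replace(partition, C=C, eps=eps, semicanonical=True)


def ccs_excitation_vectors(
    reference: SCFReference,
    n_states: int,
    dense_limit: int = 4000,
    seed: int = 0,
) -> list[tuple[float, np.ndarray]]:
    """Lowest singlet CCS (CIS) eigenpairs in the retained canonical basis.

    For an RHF reference the CCS ground state has vanishing singles, so the
    singles-singles Jacobian block is the CIS matrix
    A_{ai,bj} = delta (eps_a - eps_i) + 2(ia|jb) - (ij|ab).
    Returns (omega, R[i, a]) pairs with Frobenius-normalized R.
    """
    C, eps, no, nv = _retained_canonical(reference)
    Co, Cv = C[:, :no], C[:, no:]
    g = reference.ints.g
    g_iajb = np.einsum("abcd,ai,bp,cj,dq->ipjq", g, Co, Cv, Co, Cv, optimize=True)
    g_ijab = np.einsum("abcd,ai,bj,cp,dq->ijpq", g, Co, Co, Cv, Cv, optimize=True)
    dim = no * nv
    n_states = min(n_states, dim)
    A = (2.0 * g_iajb.transpose(0, 1, 2, 3) - g_ijab.transpose(0, 2, 1, 3))
    A = A.reshape(dim, dim)
    A += np.diag((eps[no:][None, :] - eps[:no][:, None]).ravel())
    if dim <= dense_limit:
        wvals, wvecs = sla.eigh(0.5 * (A + A.T))
        out = []
        for k in range(n_states):
            R = wvecs[:, k].reshape(no, nv)
            out.append((float(wvals[k]), R / np.linalg.norm(R)))
        return out
    diag = np.diag(A).copy()
    res = davidson_nonsym(lambda v: A @ v, diag, n_states, tol=1e-8, seed=seed)
    return [
        (float(res.values[k]),
         (res.vectors[:, k] / np.linalg.norm(res.vectors[:, k])).reshape(no, nv))
        for k in range(n_states)
    ]


def _retained_canonical(reference: SCFReference):
    """Canonicalized retained occ/virt blocks and their orbital energies."""
    no = reference.n_occ_active
    nv = reference.n_virt
    Cr = reference.C_retained
    blocks = [slice(0, no), slice(no, no + nv)]
    C, eps = canonicalize_blocks(reference.F_ao, Cr, blocks)
    return C, eps, no, nv


def approximate_doubles(
    R1: np.ndarray,
    omega_ccs: float,
    eps_occ: np.ndarray,
    eps_virt: np.ndarray,
    g_mo: np.ndarray | None = None,
    cderi: CholeskyERI | None = None,
    level_shift: float = 1e-6,
) -> np.ndarray:
    """CIS(D)-style approximate doubles R2[i,a,j,b] from a CCS vector.

    The doubles are the first-order response of the doubles residual to the
    single excitation: one-index transformed integrals divided by the
    (shifted) orbital-energy denominator eps_ab^ij - omega.  Symmetric under
    (ia) <-> (jb) by construction; zero R1 gives zero R2.
    """
    no, nv = R1.shape
    if g_mo is None:
        if cderi is None:
            raise ValueError("need either g_mo or cderi")
        from .cholesky import reconstruct_mo_integrals

        g_mo = reconstruct_mo_integrals(cderi)
    # one-index transforms of (ai|bj) along the excitation direction
    b = (
        -np.einsum("ka,kibj->iajb", R1, g_mo[:no, :no, no:, :no], optimize=True)
        + np.einsum("ic,acbj->iajb", R1, g_mo[no:, no:, no:, :no], optimize=True)
        - np.einsum("kb,aikj->iajb", R1, g_mo[no:, :no, :no, :no], optimize=True)
        + np.einsum("jc,aibc->iajb", R1, g_mo[no:, :no, no:, no:], optimize=True)
    )
    denom = (
        eps_virt[None, :, None, None] + eps_virt[None, None, None, :]
        - eps_occ[:, None, None, None] - eps_occ[None, None, :, None]
        - omega_ccs
    )
    small = np.abs(denom) < level_shift
    if np.any(small):
        warnings.warn(
            f"{int(small.sum())} near-singular CIS(D) denominators; "
            f"level shift {level_shift:g} applied",
            stacklevel=2,
        )
        denom = np.where(small, np.copysign(level_shift, denom), denom)
    return -b / denom


def build_cnto_matrices(states: list[tuple[np.ndarray, np.ndarray | None]]) -> CNTODensities:
    """Occupied/virtual CNTO matrices from (R1, R2) excitation vectors.

    For several states the single-state matrices are summed element-wise.
    Both matrices are Gram-type and therefore symmetric positive
    semidefinite.
    """
    if not states:
        raise ValueError("at least one state required")
    no, nv = states[0][0].shape
    M = np.zeros((no, no))
    N = np.zeros((nv, nv))
    for R1, R2 in states:
        M += R1 @ R1.T
        N += R1.T @ R1
        if R2 is not None:
            M += 0.5 * np.einsum("iajb,kajb->ik", R2, R2, optimize=True)
            N += 0.5 * np.einsum("iajb,icjb->ac", R2, R2, optimize=True)
    M = 0.5 * (M + M.T)
    N = 0.5 * (N + N.T)
    return CNTODensities(M=M, N=N, states=[(None, R1, R2) for R1, R2 in states])


def ratio_rule_virtuals(n_o_a: int, n_occ: int, n_virt: int) -> int:
    """Active virtual count from the virtual-to-occupied fraction (round half up)."""
    import math

    return min(n_virt, int(math.floor(n_o_a * n_virt / n_occ + 0.5)))


def select_active_space(
    densities: CNTODensities,
    C_occ: np.ndarray,
    C_virt: np.ndarray,
    n_o_a: int,
    n_v_a: int | None = None,
    tie_tol: float = 1e-12,
) -> OrbitalPartition:
    """Top-eigenvalue CNTO selection of the active space.

    ``n_v_a=None`` invokes the virtual/occupied ratio rule.  Eigenvalue ties
    exactly at the cut are resolved by including the tied orbitals (with a
    warning) to keep the selection basis-independent.
    """
    no, nv = C_occ.shape[1], C_virt.shape[1]
    if not (0 <= n_o_a <= no):
        raise ValueError(f"n_o_a={n_o_a} outside [0, {no}]")
    if n_v_a is None:
        n_v_a = ratio_rule_virtuals(n_o_a, no, nv) if n_o_a else 0
    if not (0 <= n_v_a <= nv):
        raise ValueError(f"n_v_a={n_v_a} outside [0, {nv}]")
    lo, Uo = sla.eigh(densities.M)
    lv, Uv = sla.eigh(densities.N)
    lo, Uo = lo[::-1], Uo[:, ::-1]
    lv, Uv = lv[::-1], Uv[:, ::-1]
    n_o_a = _extend_for_ties(lo, n_o_a, tie_tol, "occupied")
    n_v_a = _extend_for_ties(lv, n_v_a, tie_tol, "virtual")
    # active first in eigenvector order; reorder to (inactive | active) occ
    C_occ_new = np.hstack([C_occ @ Uo[:, n_o_a:], C_occ @ Uo[:, :n_o_a]])
    C_virt_new = np.hstack([C_virt @ Uv[:, :n_v_a], C_virt @ Uv[:, n_v_a:]])
    return OrbitalPartition(
        C=np.hstack([C_occ_new, C_virt_new]),
        n_occ_inactive=no - n_o_a,
        n_occ_active=n_o_a,
        n_virt_active=n_v_a,
        n_virt_inactive=nv - n_v_a,
        provenance="cnto",
    )


def _extend_for_ties(lam: np.ndarray, n: int, tol: float, label: str) -> int:
    while 0 < n < lam.size and abs(lam[n - 1] - lam[n]) <= tol * max(1.0, abs(lam[0])):
        warnings.warn(
            f"degenerate {label} CNTO eigenvalue at the active-space cut; "
            f"including the tied orbital",
            stacklevel=3,
        )
        n += 1
    return n


def partition_from_regions(
    reference: SCFReference,
    active_aos,
    pivot_tol: float = 1e-2,
    lindep_tol: float = 1e-6,
) -> OrbitalPartition:
    """Cholesky-occupied / PAO-virtual partition of the retained space."""
    S = reference.ints.S
    no = reference.n_occ_active
    C, eps, no_r, nv_r = _retained_canonical(reference)
    Co, Cv = C[:, :no_r], C[:, no_r:]
    D = Co @ Co.T
    C_oa, C_oi = cholesky_occupied_orbitals(D, S, active_aos, Co, pivot_tol)
    C_va, C_vi = construct_paos(D, S, active_aos, lindep_tol, C_virt_span=Cv)
    return OrbitalPartition(
        C=np.hstack([C_oi, C_oa, C_va, C_vi]),
        n_occ_inactive=C_oi.shape[1],
        n_occ_active=C_oa.shape[1],
        n_virt_active=C_va.shape[1],
        n_virt_inactive=C_vi.shape[1],
        provenance="cholesky-pao",
    )


def full_partition(reference: SCFReference) -> OrbitalPartition:
    """Everything active (parent-method limit)."""
    C, eps, no, nv = _retained_canonical(reference)
    return OrbitalPartition(
        C=C, n_occ_inactive=0, n_occ_active=no,
        n_virt_active=nv, n_virt_inactive=0,
        semicanonical=True, eps=eps, provenance="canonical",
    )


def empty_partition(reference: SCFReference) -> OrbitalPartition:
    """Nothing active (lower-level-method limit)."""
    C, eps, no, nv = _retained_canonical(reference)
    return OrbitalPartition(
        C=C, n_occ_inactive=no, n_occ_active=0,
        n_virt_active=0, n_virt_inactive=nv,
        semicanonical=True, eps=eps, provenance="canonical",
    )


def export_partition(partition: OrbitalPartition) -> dict:
    """Plain-array export of the partition blocks (for visualization)."""
    sl = partition.block_slices()
    labels = ("occ_inactive", "occ_active", "virt_active", "virt_inactive")
    out = {name: partition.C[:, s].copy() for name, s in zip(labels, sl)}
    out["semicanonical"] = np.array(partition.semicanonical)
    out["provenance"] = np.array(partition.provenance)
    if partition.eps is not None:
        out["orbital_energies"] = partition.eps.copy()
    return out
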