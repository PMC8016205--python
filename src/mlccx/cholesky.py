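"""Two-step pivoted Cholesky factorization of the electron-repulsion matrix.

Step one selects the Cholesky basis (the pivot set) by greedy max-diagonal
pivoting, optionally on an MO-screened diagonal; step two builds the factor
vectors directly in the MO basis through the RI-like expression

    L^J_pq = sum_K (pq|K) [Q^{-T}]_{KJ},   Q Q^T = S_KL = (K|L),

so AO-basis vectors are never stored.  Storage scales as n_MO^2 N_J.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .integrals import AOIntegralSet

DEFAULT_TAU_UNSCREENED = 1e-3
DEFAULT_TAU_SCREENED = 1e-4


class CholeskyBreakdownError(RuntimeError):
    pass


class InCorePairProvider:
    """Pair-matrix view (K|L) of an in-core chemist ERI tensor.

    Pairs K = (alpha, beta) with alpha >= beta are enumerated in packed
    row-major order; the provider exposes the diagonal (K|K) and single
    columns (.|K), which is all both Cholesky steps require.
    """

    def __init__(self, g: np.ndarray, ao_atoms: np.ndarray | None = None):
        self.g = g
        self.n_ao = g.shape[0]
        self.ao_atoms = ao_atoms
        tri = np.tril_indices(self.n_ao)
        self.pair_alpha, self.pair_beta = tri[0], tri[1]
        self.n_pair = self.pair_alpha.size

    @classmethod
    def from_integrals(cls, ints: AOIntegralSet) -> "InCorePairProvider":
        return cls(ints.g, ints.ao_atoms)

    def pair_index(self, alpha: int, beta: int) -> int:
        a, b = max(alpha, beta), min(alpha, beta)
        return a * (a + 1) // 2 + b

    def diagonal(self) -> np.ndarray:
        d = self.g[self.pair_alpha, self.pair_beta,
                   self.pair_alpha, self.pair_beta]
        return np.array(d, dtype=float)

    def column(self, k: int) -> np.ndarray:
        a, b = self.pair_alpha[k], self.pair_beta[k]
        return self.g[self.pair_alpha, self.pair_beta, a, b].astype(float)

    def column_matrix(self, k: int) -> np.ndarray:
        """(.|K) as a symmetric n_ao x n_ao matrix."""
        a, b = self.pair_alpha[k], self.pair_beta[k]
        return np.array(self.g[:, :, a, b], dtype=float)

    def mo_diagonal(self, C: np.ndarray) -> np.ndarray:
        """Exact MO pair diagonal (pq|pq), used to audit screened runs."""
        nmo = C.shape[1]
        out = np.empty((nmo, nmo))
        for p in range(nmo):
            m = np.einsum("abcd,a,c->bd", self.g, C[:, p], C[:, p], optimize=True)
            out[p] = np.einsum("bd,bq,dq->q", m, C, C, optimize=True)
        return out


@dataclass
class CholeskyBasis:
    """Ordered pivot set of the decomposition plus its provenance."""

    pivots: list[tuple[int, int]]
    pivot_flat: list[int]
    tau: float
    screen: bool = False
    weights: np.ndarray | None = None
    max_diag_final: float = 0.0
    max_screened_diag_final: float = 0.0
    diag_history: list[float] = field(default_factory=list)
    lower_factor: np.ndarray | None = None  # pair-space factor rows (n_pair, N_J)

    @property
    def n_vectors(self) -> int:
        return len(self.pivots)


def screening_weights(C_active: np.ndarray) -> np.ndarray:
    """Per-AO screening factors w_alpha = (sum_p |C^a_{alpha p}|)^2.

    The screened diagonal D~_{ab} = D_{ab} w_a w_b is a Cauchy-Schwarz style
    upper-bound surrogate for the diagonal of the MO-projected integral
    matrix; rows of C that carry no active MO weight are screened out.
    """
    C_active = np.atleast_2d(np.asarray(C_active, dtype=float))
    return np.sum(np.abs(C_active), axis=1) ** 2


def find_cholesky_basis(
    provider: InCorePairProvider,
    tau: float,
    screen_weights: np.ndarray | None = None,
    mo_coefficients: np.ndarray | None = None,
    prescreen_factor: float = 1e-2,
    max_vectors: int | None = None,
) -> CholeskyBasis:
    """Greedy max-diagonal pivot selection (step one of the decomposition).

    Unscreened mode terminates when the maximum residual diagonal is <= tau,
    which bounds every AO reconstruction error by tau.  Screened mode pivots
    on D~ = D * w_a * w_b and terminates when max D~ <= tau *and* the exact
    MO-projected residual diagonal (audited with ``mo_coefficients``) is
    <= tau, making the MO-basis error guarantee rigorous.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    d = provider.diagonal().copy()
    if d.min() < -1e-12:
        raise CholeskyBreakdownError(
            f"initial diagonal has entry {d.min():.3e} below -1e-12"
        )
    np.clip(d, 0.0, None, out=d)
    d0max = d.max() if d.size else 0.0
    screen = screen_weights is not None
    if screen:
        w = np.asarray(screen_weights, dtype=float)
        wpair = w[provider.pair_alpha] * w[provider.pair_beta]
    else:
        w = None
        wpair = np.ones_like(d)
    candidate = d >= tau * prescreen_factor
    nmax = max_vectors if max_vectors is not None else provider.n_pair
    pivots: list[int] = []
    history: list[float] = []
    L = np.zeros((provider.n_pair, 0))

    def residual_column(k: int) -> np.ndarray:
        col = provider.column(k)
        if pivots:
            col = col - L[:, : len(pivots)] @ L[k, : len(pivots)]
        return col

    audit_needed = screen and mo_coefficients is not None
    mo_diag_exact = None
    tau_eff = tau
    while True:
        dscr = np.where(candidate, d * wpair, 0.0)
        kmax = int(np.argmax(dscr))  # ties: lowest pair index (argmax first hit)
        if dscr[kmax] <= tau_eff or len(pivots) >= nmax:
            if not audit_needed or len(pivots) >= nmax:
                break
            # screened run: audit the exact MO-projected residual diagonal
            if mo_diag_exact is None:
                mo_diag_exact = provider.mo_diagonal(mo_coefficients)
            mo_res = mo_diag_exact.copy()
            if pivots:
                y = np.stack([
                    _pair_to_mo(L[:, j], provider, mo_coefficients)
                    for j in range(len(pivots))
                ])
                mo_res = mo_res - np.einsum("jpq,jpq->pq", y, y)
            if mo_res.max() <= tau:
                break
            # surrogate bound was too loose here: tighten and keep pivoting
            tau_eff *= 0.1
            candidate |= d >= tau_eff * prescreen_factor
            candidate[pivots] = False
            continue
        if d[kmax] < -10 * np.finfo(float).eps * max(d0max, 1.0):
            raise CholeskyBreakdownError(
                f"negative updated diagonal {d[kmax]:.3e} at pivot {kmax}"
            )
        col = residual_column(kmax)
        piv_val = max(d[kmax], 0.0)
        if piv_val <= 0.0:
            candidate[kmax] = False
            continue
        ell = col / np.sqrt(piv_val)
        L = np.hstack([L, ell[:, None]])
        d -= ell * ell
        low = d < -10 * np.finfo(float).eps * max(d0max, 1.0)
        if np.any(low):
            raise CholeskyBreakdownError(
                f"residual diagonal dipped to {d.min():.3e} after pivot {kmax}"
            )
        np.clip(d, 0.0, None, out=d)
        pivots.append(kmax)
        candidate[kmax] = False
        history.append(float(dscr[kmax]))
    pairs = [(int(provider.pair_alpha[k]), int(provider.pair_beta[k])) for k in pivots]
    return CholeskyBasis(
        pivots=pairs,
        pivot_flat=list(pivots),
        tau=tau,
        screen=screen,
        weights=w,
        max_diag_final=float(d.max()) if d.size else 0.0,
        max_screened_diag_final=float((d * (wpair if screen else 1.0)).max()) if d.size else 0.0,
        diag_history=history,
        lower_factor=L,
    )


def _pair_to_mo(col: np.ndarray, provider: InCorePairProvider, C: np.ndarray) -> np.ndarray:
    """Lift a packed-pair vector to the symmetric AO matrix and MO-transform."""
    n = provider.n_ao
    m = np.zeros((n, n))
    m[provider.pair_alpha, provider.pair_beta] = col
    m[provider.pair_beta, provider.pair_alpha] = col
    return C.T @ m @ C


def build_q_inverse(basis: CholeskyBasis, provider: InCorePairProvider) -> np.ndarray:
    """Inverse lower Cholesky factor of S_KL = (K|L) on the pivot pairs."""
    idx = basis.pivot_flat
    nj = len(idx)
    if nj == 0:
        return np.zeros((0, 0))
    Skl = np.empty((nj, nj))
    for j, k in enumerate(idx):
        col = provider.column(k)
        Skl[:, j] = col[idx]
    Skl = 0.5 * (Skl + Skl.T)
    try:
        Q = sla.cholesky(Skl, lower=True)
    except sla.LinAlgError as exc:
        raise CholeskyBreakdownError(
            "pivot overlap matrix S_KL is numerically singular; "
            "increase the decomposition threshold tau"
        ) from exc
    return sla.solve_triangular(Q, np.eye(nj), lower=True)


@dataclass
class CholeskyERI:
    """MO-basis Cholesky factors L^J_pq with their provenance."""

    L: np.ndarray  # (N_J, n_mo, n_mo)
    basis: CholeskyBasis
    n_mo: int

    @property
    def n_vectors(self) -> int:
        return self.L.shape[0]

    def rotate(self, U: np.ndarray) -> "CholeskyERI":
        """Unitary MO-basis rotation of the factors (L' = U^T L U)."""
        Lr = np.einsum("jpq,pa,qb->jab", self.L, U, U, optimize=True)
        return CholeskyERI(L=Lr, basis=self.basis, n_mo=U.shape[1])


def build_mo_vectors(
    basis: CholeskyBasis,
    q_inverse: np.ndarray,
    C: np.ndarray,
    provider: InCorePairProvider,
    max_batch: int | None = None,
) -> CholeskyERI:
    """Assemble L^J_pq directly in the MO basis (step two, Algorithm-style).

    The AO columns (alphabeta|K) are contracted with C on both AO indices
    and then with Q^{-1}; batching over the first MO index p gives identical
    results for any ``max_batch``.
    """
    n_mo = C.shape[1]
    nj = basis.n_vectors
    if nj == 0:
        return CholeskyERI(L=np.zeros((0, n_mo, n_mo)), basis=basis, n_mo=n_mo)
    if max_batch is None or max_batch <= 0:
        max_batch = n_mo
    # X[K, p, q] = (pq|K), built per K then batched over p for the Q^{-1} step
    X = np.empty((nj, n_mo, n_mo))
    for j, k in enumerate(basis.pivot_flat):
        A = provider.column_matrix(k)
        X[j] = C.T @ A @ C
    L = np.empty((nj, n_mo, n_mo))
    for p0 in range(0, n_mo, max_batch):
        p1 = min(p0 + max_batch, n_mo)
        # L^J_{pq} = sum_K Qinv[J, K] X[K, p, q] for the p-batch
        L[:, p0:p1, :] = np.tensordot(q_inverse, X[:, p0:p1, :], axes=(1, 0))
    L = 0.5 * (L + L.transpose(0, 2, 1))
    return CholeskyERI(L=L, basis=basis, n_mo=n_mo)


def reconstruct_mo_integrals(cderi: CholeskyERI) -> np.ndarray:
    """4-index MO ERI tensor g_pqrs = sum_J L^J_pq L^J_rs."""
    n = cderi.n_mo
    if cderi.n_vectors == 0:
        return np.zeros((n, n, n, n))
    return np.einsum("jpq,jrs->pqrs", cderi.L, cderi.L, optimize=True)


def decompose(
    ints: AOIntegralSet,
    C: np.ndarray,
    tau: float = DEFAULT_TAU_UNSCREENED,
    screen: bool = False,
    C_active: np.ndarray | None = None,
    max_batch: int | None = None,
) -> CholeskyERI:
    """Convenience driver: pivot selection, Q inversion, MO vector build."""
    provider = InCorePairProvider.from_integrals(ints)
    weights = None
    mo_coeff = None
    if screen:
        Ca = C_active if C_active is not None else C
        weights = screening_weights(Ca)
        mo_coeff = Ca
    basis = find_cholesky_basis(
        provider, tau, screen_weights=weights, mo_coefficients=mo_coeff
    )
    if basis.n_vectors == 0:
        warnings.warn("Cholesky decomposition selected zero pivots", stacklevel=2)
    qinv = build_q_inverse(basis, provider)
    return build_mo_vectors(basis, qinv, C, provider, max_batch=max_batch)


def save_cderi(path: str, cderi: CholeskyERI, key: str) -> None:
    """Cache MO-basis factors in an HDF5 container under a run key.

    ``key`` should identify (geometry hash, basis, tau, screening mode);
    see :func:`cache_key`.
    """
    import h5py

    with h5py.File(path, "a") as fh:
        if key in fh:
            del fh[key]
        grp = fh.create_group(key)
        grp.create_dataset("L", data=cderi.L)
        grp.attrs["tau"] = cderi.basis.tau
        grp.attrs["screen"] = cderi.basis.screen
        grp.attrs["n_mo"] = cderi.n_mo
        grp.create_dataset("pivots", data=np.array(cderi.basis.pivots))


def load_cderi(path: str, key: str) -> CholeskyERI | None:
    """Load cached factors; returns None on a cache miss."""
    import h5py

    try:
        with h5py.File(path, "r") as fh:
            if key not in fh:
                return None
            grp = fh[key]
            pivots = [tuple(int(x) for x in row) for row in grp["pivots"][()]]
            basis = CholeskyBasis(
                pivots=pivots, pivot_flat=[], tau=float(grp.attrs["tau"]),
                screen=bool(grp.attrs["screen"]),
            )
            return CholeskyERI(L=grp["L"][()], basis=basis,
                               n_mo=int(grp.attrs["n_mo"]))
    except OSError:
        return None


def cache_key(system, basis_label: str, tau: float, screen: bool) -> str:
    """Deterministic cache key from geometry, basis and decomposition mode."""
    import hashlib

    h = hashlib.sha256()
    h.update(np.round(system.coords, 10).tobytes())
    h.update("".join(system.atoms).encode())
    h.update(f"{basis_label}|{tau:.3e}|{int(screen)}".encode())
    return h.hexdigest()[:24]
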