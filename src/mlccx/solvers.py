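"""Shared iterative machinery: DIIS acceleration and a non-symmetric Davidson.

Both solvers operate on flat real vectors and know nothing about coupled
cluster; the CC modules supply matrix-free operator contracts and diagonal
preconditioners (orbital-energy differences).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import scipy.linalg as sla


class ConvergenceError(RuntimeError):
    pass


class ComplexRitzError(RuntimeError):
    """A requested Ritz pair came out complex (non-symmetric operator)."""


@dataclass
class DIISState:
    """Ring buffer of (parameter, error) pairs for Pulay extrapolation."""

    max_size: int = 8
    params: list = field(default_factory=list)
    errors: list = field(default_factory=list)
    last_coefficients: np.ndarray | None = None

    def push(self, param: np.ndarray, error: np.ndarray) -> None:
        self.params.append(np.array(param, dtype=float))
        self.errors.append(np.array(error, dtype=float))
        if len(self.params) > self.max_size:
            self.params.pop(0)
            self.errors.pop(0)


def diis_step(state: DIISState, new_param: np.ndarray, new_error: np.ndarray) -> np.ndarray:
    """Append the new pair and return the DIIS-extrapolated parameter.

    Solves the constrained least-squares problem min ||sum_i c_i e_i|| with
    sum_i c_i = 1.  On a singular B matrix the oldest vectors are dropped;
    as a last resort the plain (unextrapolated) parameter is returned.
    """
    state.push(new_param, new_error)
    while True:
        n = len(state.params)
        if n == 1:
            state.last_coefficients = np.array([1.0])
            return state.params[0].copy()
        B = np.empty((n + 1, n + 1))
        B[:n, :n] = [[float(np.dot(ei, ej)) for ej in state.errors] for ei in state.errors]
        B[n, :n] = B[:n, n] = -1.0
        B[n, n] = 0.0
        rhs = np.zeros(n + 1)
        rhs[n] = -1.0
        try:
            sol = np.linalg.solve(B, rhs)
        except np.linalg.LinAlgError:
            sol = None
        if sol is not None and np.all(np.isfinite(sol)):
            c = sol[:n]
            state.last_coefficients = c
            out = np.zeros_like(state.params[0])
            for ci, pi in zip(c, state.params):
                out += ci * pi
            return out
        if n > 2:
            state.params.pop(0)
            state.errors.pop(0)
        else:
            state.last_coefficients = np.array([0.0, 1.0])
            return state.params[-1].copy()


@dataclass
class DavidsonResult:
    values: np.ndarray
    vectors: np.ndarray  # columns
    residual_norms: np.ndarray
    n_iterations: int
    history: list = field(default_factory=list)


def davidson_nonsym(
    apply_A: Callable[[np.ndarray], np.ndarray],
    diag: np.ndarray,
    n_roots: int,
    tol: float = 1e-6,
    seed: int = 0,
    max_iter: int = 200,
    start_vectors: Sequence[np.ndarray] | None = None,
    subspace_cap_factor: int = 20,
) -> DavidsonResult:
    """Lowest right eigenpairs of a real non-symmetric operator.

    ``apply_A`` maps a vector to A @ v; ``diag`` is a diagonal estimate used
    for preconditioning and for the deterministic unit-vector start guess.
    Deterministic for a fixed seed (the seed only perturbs degenerate start
    guesses by a tiny amount to break exact ties).
    """
    n = diag.shape[0]
    if n_roots > n:
        raise ValueError(f"requested {n_roots} roots from a dimension-{n} operator")
    if n_roots < 1:
        raise ValueError("n_roots must be >= 1")
    rng = np.random.default_rng(seed)
    cap = max(subspace_cap_factor * n_roots, 3 * n_roots + 6)
    cap = min(cap, n)
    nb0 = min(max(2 * n_roots, n_roots + 2), n)
    if start_vectors is not None:
        V = np.array([v / np.linalg.norm(v) for v in start_vectors]).T
    else:
        order = np.argsort(diag, kind="stable")
        V = np.zeros((n, nb0))
        for k in range(nb0):
            V[order[k], k] = 1.0
            V[:, k] += 1e-8 * rng.standard_normal(n)
            V[:, k] /= np.linalg.norm(V[:, k])
    V = _orthonormalize(V)
    W = np.column_stack([apply_A(V[:, k]) for k in range(V.shape[1])])
    history: list[np.ndarray] = []
    imag_streak = 0
    for it in range(max_iter):
        H = V.T @ W
        theta, Y = sla.eig(H)
        # sort by real part; track complex pairs
        order = np.argsort(theta.real, kind="stable")
        theta, Y = theta[order], Y[:, order]
        sel = slice(0, n_roots)
        imag_bad = np.any(
            np.abs(theta[sel].imag) > 1e-8 * (1.0 + np.abs(theta[sel].real))
        )
        imag_streak = imag_streak + 1 if imag_bad else 0
        if imag_bad and (V.shape[1] >= n or imag_streak > 25):
            # persistent complex pair: a property of A, not of the subspace
            raise ComplexRitzError(
                f"complex Ritz value among the lowest {n_roots} roots: {theta[sel]}"
            )
        # transient complex pairs in a partial subspace: iterate on real parts
        vals = theta[sel].real
        y = Y[:, sel].real
        X = V @ y
        AX = W @ y
        resid = AX - X * vals[None, :]
        rnorms = np.linalg.norm(resid, axis=0)
        history.append(rnorms.copy())
        if np.all(rnorms <= tol) and not imag_bad:
            # normalize eigenvectors
            X = X / np.linalg.norm(X, axis=0)[None, :]
            return DavidsonResult(vals, X, rnorms, it + 1, history)
        if V.shape[1] + n_roots > cap:
            # collapse to current Ritz vectors; duplicate columns from the
            # real parts of complex pairs may drop out, so pad if needed
            keep = min(2 * n_roots, X.shape[1])
            V = _orthonormalize(X[:, :keep])
            while V.shape[1] < min(n_roots + 1, n):
                pad = _orthonormalize(
                    rng.standard_normal((n, 1)), against=V
                )
                if pad.shape[1] == 0:
                    break
                V = np.hstack([V, pad])
            W = np.column_stack([apply_A(V[:, k]) for k in range(V.shape[1])])
            continue
        new_dirs = []
        for k in range(n_roots):
            if rnorms[k] <= tol:
                continue
            denom = diag - vals[k]
            denom = np.where(np.abs(denom) < 1e-6, np.copysign(1e-6, denom), denom)
            t = -resid[:, k] / denom
            t = t - V @ (V.T @ t)
            t = t - V @ (V.T @ t)
            nt = np.linalg.norm(t)
            if nt > 1e-10:
                new_dirs.append(t / nt)
        if not new_dirs:
            X = X / np.linalg.norm(X, axis=0)[None, :]
            return DavidsonResult(vals, X, rnorms, it + 1, history)
        T = _orthonormalize(np.column_stack(new_dirs), against=V)
        if T.shape[1] == 0:
            X = X / np.linalg.norm(X, axis=0)[None, :]
            return DavidsonResult(vals, X, rnorms, it + 1, history)
        V = np.hstack([V, T])
        W = np.hstack([W, np.column_stack([apply_A(T[:, k]) for k in range(T.shape[1])])])
    raise ConvergenceError(
        f"Davidson did not converge in {max_iter} iterations; "
        f"residual norms {history[-1]}"
    )


def _orthonormalize(V: np.ndarray, against: np.ndarray | None = None) -> np.ndarray:
    """Orthonormalize columns (optionally also against an orthonormal set)."""
    cols = []
    for k in range(V.shape[1]):
        v = V[:, k].copy()
        for _ in range(2):
            if against is not None:
                v -= against @ (against.T @ v)
            for u in cols:
                v -= u * (u @ v)
        nv = np.linalg.norm(v)
        if nv > 1e-10:
            cols.append(v / nv)
    if not cols:
        return np.zeros((V.shape[0], 0))
    return np.column_stack(cols)
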