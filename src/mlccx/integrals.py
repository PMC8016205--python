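"""AO integral computation behind a pluggable provider contract.

The default provider evaluates overlap, core Hamiltonian and the full
in-core ERI tensor (chemist notation, 8-fold symmetric) with the
McMurchie-Davidson kernels in :mod:`mlccx._mdint`.  Desk scale only: the
ERI tensor is O(N_AO^4) in memory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Protocol

import numpy as np

from . import _mdint
from .basis import BasisError, build_shells
from .system import MolecularSystem


@dataclass
class AOIntegralSet:
    """AO-basis integrals: overlap S, core Hamiltonian h, ERIs g (chemist)."""

    S: np.ndarray
    hcore: np.ndarray
    g: np.ndarray  # g[a, b, c, d] = (ab|cd)
    n_ao: int
    ao_atoms: np.ndarray
    enuc: float

    def pair_diagonal(self) -> np.ndarray:
        """Diagonal (ab|ab) of the ERI matrix over AO pairs, shape (n,n)."""
        n = self.n_ao
        d = np.empty((n, n))
        for a in range(n):
            d[a] = self.g[a, :, a, :].diagonal()
        return d


class IntegralProvider(Protocol):
    def compute(self, system: MolecularSystem) -> AOIntegralSet: ...


def _prim_norm(l: int, alpha: float) -> float:
    dfact = 1.0
    for k in range(2 * l - 1, 0, -2):
        dfact *= k
    return (2.0 * alpha / math.pi) ** 0.75 * (4.0 * alpha) ** (l / 2.0) / math.sqrt(dfact)


class MDIntegralProvider:
    """In-repo McMurchie-Davidson integral engine."""

    def __init__(self, screen_tol: float = 1e-14):
        self.screen_tol = screen_tol

    def compute(self, system: MolecularSystem) -> AOIntegralSet:
        shells, ao_atoms = build_shells(system)
        nsh = len(shells)
        sh_l = np.array([s.l for s in shells], dtype=np.int64)
        sh_np = np.array([len(s.exps) for s in shells], dtype=np.int64)
        sh_ps = np.zeros(nsh, dtype=np.int64)
        off = 0
        exps, coefs = [], []
        for i, s in enumerate(shells):
            sh_ps[i] = off
            off += len(s.exps)
            exps.append(s.exps)
            coefs.append(s.coefs * np.array([_prim_norm(s.l, a) for a in s.exps]))
        prim_exp = np.concatenate(exps)
        prim_coef = np.concatenate(coefs)
        sh_c = np.array([s.center for s in shells])
        sh_ao = np.zeros(nsh, dtype=np.int64)
        n = 0
        for i, s in enumerate(shells):
            sh_ao[i] = n
            n += s.ncart
        nao = n
        atom_xyz = system.coords * 1.8897259886
        atom_z = system.charges
        S = np.zeros((nao, nao))
        T = np.zeros((nao, nao))
        V = np.zeros((nao, nao))
        _mdint.one_electron(sh_l, sh_np, sh_ps, sh_c, sh_ao, prim_exp,
                            prim_coef, atom_xyz, atom_z, nao, S, T, V)
        g = np.zeros((nao, nao, nao, nao))
        _mdint.eri_tensor(sh_l, sh_np, sh_ps, sh_c, sh_ao, prim_exp,
                          prim_coef, nao, self.screen_tol, g)
        # normalize each contracted cartesian AO to unit self-overlap
        d = 1.0 / np.sqrt(np.diag(S))
        S = S * d[:, None] * d[None, :]
        h = (T + V) * d[:, None] * d[None, :]
        g = np.einsum("abcd,a,b,c,d->abcd", g, d, d, d, d, optimize=True)
        return AOIntegralSet(
            S=S, hcore=h, g=g, n_ao=nao, ao_atoms=ao_atoms,
            enuc=system.nuclear_repulsion(),
        )


_default_provider = MDIntegralProvider()


def compute_ao_integrals(
    system: MolecularSystem, provider: IntegralProvider | None = None
) -> AOIntegralSet:
    """Compute the AO integral set for a system (see :class:`AOIntegralSet`).

    Raises :class:`mlccx.basis.BasisError` for unresolvable basis labels.
    """
    prov = provider if provider is not None else _default_provider
    return prov.compute(system)


__all__ = [
    "AOIntegralSet",
    "BasisError",
    "IntegralProvider",
    "MDIntegralProvider",
    "compute_ao_integrals",
]
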