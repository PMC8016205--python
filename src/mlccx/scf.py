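"""Restricted Hartree-Fock reference and frozen-Fock reduced-space embedding.

Conventions (fixed package-wide):

* the one-particle density is D = C_occ C_occ^T (idempotent under D S D = D);
  all factors of 2 for double occupation live in the Fock/energy expressions;
* frozen orbitals (core or environment) enter the correlated equations only
  through their mean-field contribution F^f = 2 J(D_f) - K(D_f) folded into
  an effective core Hamiltonian.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.linalg as sla

from .integrals import AOIntegralSet
from .solvers import DIISState, diis_step
from .system import CORE_ORBITALS, ELEMENTS, MolecularSystem


class SCFConvergenceError(RuntimeError):
    pass


@dataclass
class SCFReference:
    """A (possibly rotated / reduced) closed-shell mean-field reference.

    ``C`` holds the retained MOs ordered (frozen-occ | occ | virt); the first
    ``n_frozen`` columns are frozen and contribute only through
    ``F_frozen_ao``.  For a plain converged RHF solution ``n_frozen`` is 0 and
    ``C`` spans the full AO space.
    """

    ints: AOIntegralSet
    C: np.ndarray
    eps: np.ndarray | None
    F_ao: np.ndarray
    energy: float
    n_occ: int  # total occupied count including frozen
    n_frozen: int = 0
    F_frozen_ao: np.ndarray | None = None

    @property
    def n_mo(self) -> int:
        return self.C.shape[1]

    @property
    def n_occ_active(self) -> int:
        """Occupied orbitals retained in the correlated treatment."""
        return self.n_occ - self.n_frozen

    @property
    def n_virt(self) -> int:
        return self.n_mo - self.n_occ

    @property
    def C_occ(self) -> np.ndarray:
        return self.C[:, : self.n_occ]

    @property
    def C_retained(self) -> np.ndarray:
        return self.C[:, self.n_frozen :]

    @property
    def D(self) -> np.ndarray:
        return self.C_occ @ self.C_occ.T

    def h_eff_ao(self) -> np.ndarray:
        """Core Hamiltonian plus the frozen-orbital mean field (Fock form)."""
        h = self.ints.hcore
        if self.n_frozen and self.F_frozen_ao is not None:
            return h + self.F_frozen_ao
        return h


def fock_matrix(ints: AOIntegralSet, D: np.ndarray) -> np.ndarray:
    """Closed-shell Fock matrix h + 2J(D) - K(D) for density D = Co Co^T."""
    J = np.einsum("abcd,cd->ab", ints.g, D, optimize=True)
    K = np.einsum("acbd,cd->ab", ints.g, D, optimize=True)
    return ints.hcore + 2.0 * J - K


def two_electron_fock(ints: AOIntegralSet, D: np.ndarray) -> np.ndarray:
    """2J(D) - K(D) only (no core Hamiltonian)."""
    J = np.einsum("abcd,cd->ab", ints.g, D, optimize=True)
    K = np.einsum("acbd,cd->ab", ints.g, D, optimize=True)
    return 2.0 * J - K


def run_rhf(
    ints: AOIntegralSet,
    system: MolecularSystem,
    gradient_tol: float = 1e-8,
    max_iter: int = 100,
    diis_size: int = 8,
) -> SCFReference:
    """Converge a closed-shell RHF reference with DIIS on FDS - SDF.

    The convergence measure is the Frobenius norm of the AO orbital gradient
    F D S - S D F; orbital energies come out ascending by diagonalization.
    """
    n_el = system.n_electrons
    if n_el % 2:
        raise ValueError("open-shell input rejected (odd electron count)")
    nocc = n_el // 2
    if nocc == 0 or nocc > ints.n_ao:
        raise ValueError(f"{nocc} occupied orbitals with {ints.n_ao} AOs")
    S, h = ints.S, ints.hcore
    F = h.copy()
    diis = DIISState(max_size=diis_size)
    grad_norm = np.inf
    eps = C = D = None
    for _ in range(max_iter):
        eps, C = sla.eigh(F, S)
        D = C[:, :nocc] @ C[:, :nocc].T
        F_new = fock_matrix(ints, D)
        grad = F_new @ D @ S - S @ D @ F_new
        grad_norm = np.linalg.norm(grad)
        if grad_norm <= gradient_tol:
            F = F_new
            break
        F = diis_step(diis, F_new.ravel(), grad.ravel()).reshape(F.shape)
    else:
        raise SCFConvergenceError(
            f"RHF did not reach |FDS-SDF| <= {gradient_tol:g} in {max_iter} "
            f"iterations (last gradient norm {grad_norm:.3e})"
        )
    eps, C = sla.eigh(F, S)
    D = C[:, :nocc] @ C[:, :nocc].T
    energy = float(np.sum(D * (h + F)) + ints.enuc)
    return SCFReference(
        ints=ints, C=C, eps=eps, F_ao=F, energy=energy, n_occ=nocc
    )


def scf_energy_from_density(ints: AOIntegralSet, D: np.ndarray) -> float:
    F = fock_matrix(ints, D)
    return float(np.sum(D * (ints.hcore + F)) + ints.enuc)


def n_core_orbitals(system: MolecularSystem) -> int:
    return sum(CORE_ORBITALS[ELEMENTS[a]] for a in system.atoms)


def build_frozen_fock(reference: SCFReference, frozen_occ) -> np.ndarray:
    """Total AO Fock split as h + (retained-occ two-electron) + F^f.

    ``frozen_occ`` is a set of occupied MO indices (columns of C).  The
    result equals the Fock matrix of the full density whenever the frozen
    set is a subset of the occupied space (linearity of J and K).
    """
    frozen = sorted(set(int(i) for i in frozen_occ))
    for i in frozen:
        if i < 0 or i >= reference.n_occ:
            raise ValueError(f"frozen index {i} is not an occupied orbital")
    occ = [i for i in range(reference.n_occ) if i not in frozen]
    Cf = reference.C[:, frozen]
    Cr = reference.C[:, occ]
    Ff = two_electron_fock(reference.ints, Cf @ Cf.T) if frozen else 0.0
    return reference.ints.hcore + two_electron_fock(reference.ints, Cr @ Cr.T) + Ff


def freeze_core(reference: SCFReference, system: MolecularSystem) -> SCFReference:
    """Move the chemical-core orbitals into the frozen set (Fock embedding).

    The lowest-energy occupied orbitals (element core counts: none for H/He,
    one for first-row atoms) are frozen; their Coulomb-exchange mean field
    F^f is recorded for folding into the effective core Hamiltonian.
    """
    nf = n_core_orbitals(system)
    if nf >= reference.n_occ:
        raise ValueError(
            f"frozen-core count {nf} >= occupied count {reference.n_occ}"
        )
    if nf == 0:
        return replace(reference, n_frozen=0, F_frozen_ao=None)
    if reference.n_frozen:
        raise ValueError("reference already has frozen orbitals")
    Cf = reference.C[:, :nf]
    Ff = two_electron_fock(reference.ints, Cf @ Cf.T)
    return replace(reference, n_frozen=nf, F_frozen_ao=Ff)


def freeze_occupied(reference: SCFReference, C_frozen: np.ndarray,
                    C_occ_retained: np.ndarray,
                    C_virt_retained: np.ndarray) -> SCFReference:
    """Build a reduced-space reference from explicit orbital blocks.

    The blocks must jointly be S-orthonormal; the frozen occupieds enter
    downstream equations only via their Fock contribution.  Virtual orbitals
    outside ``C_virt_retained`` are simply dropped (they carry no mean
    field).
    """
    S = reference.ints.S
    nf = C_frozen.shape[1]
    C = np.hstack([C_frozen, C_occ_retained, C_virt_retained])
    ortho = C.T @ S @ C
    if not np.allclose(ortho, np.eye(C.shape[1]), atol=1e-8):
        raise ValueError("orbital blocks are not jointly S-orthonormal")
    n_occ = nf + C_occ_retained.shape[1]
    Ff = two_electron_fock(reference.ints, C_frozen @ C_frozen.T) if nf else None
    return SCFReference(
        ints=reference.ints,
        C=C,
        eps=None,
        F_ao=reference.F_ao,
        energy=reference.energy,
        n_occ=n_occ,
        n_frozen=nf,
        F_frozen_ao=Ff,
    )
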