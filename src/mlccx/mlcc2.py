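"""Multilevel CC2: perturbative doubles restricted to an active orbital space.

The singles operator is unrestricted; the doubles operator and its
projection space are restricted to active occupied/virtual orbitals.  With
every orbital active the model is standard CC2; with no active orbitals it
reduces to CCS.  Excitation energies are right eigenvalues of the Jacobian
of the residual, solved matrix-free with a Davidson iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dressing
from .cholesky import CholeskyERI
from .dressing import CCAmplitudes, CCSystem, PairPacking, make_cc_system
from .orbitals import OrbitalPartition
from .scf import SCFReference

METHOD = "cc2"


@dataclass
class GroundState:
    """Converged MLCC2 ground state."""

    energy: float
    correlation_energy: float
    amplitudes: CCAmplitudes
    ccsys: CCSystem
    info: dict


def x1_transform_cholesky(ccsys: CCSystem, x1: np.ndarray):
    """X1-dressed Cholesky vectors, one-electron matrix and Fock matrix."""
    return dressing.x1_transform_cholesky(ccsys, x1)


def solve_s2(ccsys: CCSystem, x1: np.ndarray) -> np.ndarray:
    """Analytic S2 amplitudes in the semicanonical basis (one iteration)."""
    return dressing.solve_s2(ccsys, x1)


def ground_state(
    reference: SCFReference,
    partition: OrbitalPartition,
    cderi: CholeskyERI,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> GroundState:
    """Solve the MLCC2 ground state (DIIS-accelerated quasi-Newton on X1;
    S2 eliminated analytically every iteration)."""
    ccsys = make_cc_system(reference, partition, cderi)
    e, ecorr, amps, info = dressing.ground_state(
        ccsys, METHOD, tol=tol, max_iter=max_iter
    )
    return GroundState(e, ecorr, amps, ccsys, info)


def jacobian_apply(
    ccsys: CCSystem,
    amplitudes: CCAmplitudes,
    trial_vector: np.ndarray,
    packing: PairPacking | None = None,
) -> np.ndarray:
    """Matrix-free action of the MLCC2 Jacobian on a packed trial vector."""
    return dressing.jacobian_apply(ccsys, amplitudes, trial_vector, METHOD, packing)


def excited_states(
    gs: GroundState,
    n_states: int,
    tol: float = 1e-4,
    seed: int = 0,
) -> list[tuple[float, np.ndarray]]:
    """Lowest MLCC2 excitation energies (hartree) and right eigenvectors."""
    return dressing.excited_states(
        gs.ccsys, gs.amplitudes, METHOD, n_states, tol=tol, seed=seed
    )
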