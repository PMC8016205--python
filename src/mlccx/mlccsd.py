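"""Multilevel CCSD in the two-level CCS/CCSD formulation.

Unrestricted singles plus full doubles restricted to a single active
orbital space; equations are the standard closed-shell CCSD equations in
the X1-dressed basis except for the restriction of T2 and of the doubles
projection space.  Full active space recovers CCSD; empty active space
recovers CCS.  The CCS-level terms share one code path with MLCC2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import dressing
from .cholesky import CholeskyERI
from .dressing import CCAmplitudes, CCSystem, PairPacking, make_cc_system
from .orbitals import OrbitalPartition
from .scf import SCFReference

METHOD = "ccsd"


@dataclass
class GroundState:
    """Converged MLCCSD ground state."""

    energy: float
    correlation_energy: float
    amplitudes: CCAmplitudes
    ccsys: CCSystem
    info: dict


def ground_state(
    reference: SCFReference,
    partition: OrbitalPartition,
    cderi: CholeskyERI,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> GroundState:
    """Joint DIIS quasi-Newton solution of the MLCCSD amplitude equations."""
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
    """Matrix-free action of the MLCCSD Jacobian on a packed trial vector."""
    return dressing.jacobian_apply(ccsys, amplitudes, trial_vector, METHOD, packing)


def excited_states(
    gs: GroundState,
    n_states: int,
    tol: float = 1e-4,
    seed: int = 0,
) -> list[tuple[float, np.ndarray]]:
    """Lowest MLCCSD excitation energies (hartree) and right eigenvectors."""
    return dressing.excited_states(
        gs.ccsys, gs.amplitudes, METHOD, n_states, tol=tol, seed=seed
    )
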