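"""Shared fixtures: molecules, integrals, references (session-scoped)."""

from __future__ import annotations

import numpy as np
import pytest

from mlccx.integrals import compute_ao_integrals
from mlccx.scf import freeze_core, run_rhf
from mlccx.system import formaldehyde, generate_solvated_fixture, parse_xyz, water

H2_XYZ = """2
hydrogen molecule
H 0 0 0
H 0 0 0.74
"""


@pytest.fixture(scope="session")
def h2():
    system = parse_xyz(H2_XYZ)
    ints = compute_ao_integrals(system)
    ref = run_rhf(ints, system)
    return system, ints, ref


@pytest.fixture(scope="session")
def water_sto3g():
    system = water("sto-3g")
    ints = compute_ao_integrals(system)
    ref = run_rhf(ints, system)
    return system, ints, ref


@pytest.fixture(scope="session")
def water_sto3g_fc(water_sto3g):
    system, ints, ref = water_sto3g
    return system, ints, freeze_core(ref, system)


@pytest.fixture(scope="session")
def water_dz():
    system = water("cc-pvdz")
    ints = compute_ao_integrals(system)
    ref = run_rhf(ints, system)
    return system, ints, ref


@pytest.fixture(scope="session")
def water_dz_fc(water_dz):
    system, ints, ref = water_dz
    return system, ints, freeze_core(ref, system)


@pytest.fixture(scope="session")
def shell5():
    """Four waters around a central water (5 molecules, 35 AOs)."""
    system = generate_solvated_fixture(4, seed=7)
    ints = compute_ao_integrals(system)
    ref = run_rhf(ints, system)
    return system, ints, ref


@pytest.fixture(scope="session")
def ch2o_shell10():
    """Formaldehyde in a 10-water shell (82 AOs), frozen core."""
    system = generate_solvated_fixture(10, seed=42, solute=formaldehyde())
    ints = compute_ao_integrals(system)
    ref = freeze_core(run_rhf(ints, system), system)
    return system, ints, ref


def mo_eri(g_ao: np.ndarray, C: np.ndarray) -> np.ndarray:
    return np.einsum("abcd,ap,bq,cr,ds->pqrs", g_ao, C, C, C, C, optimize=True)
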