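"""Gaussian basis sets embedded as plain-text tables.

Cartesian Gaussians are used throughout (6-component d shells).  Each
contracted AO is normalized to unit self-overlap, which leaves the spanned
space (and therefore all observables) unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .system import ANGSTROM_TO_BOHR, MolecularSystem

# shell blocks: element -> list of (l, exponents, contraction coefficients)
_STO3G = {
    "H": [
        (0, [3.42525091, 0.62391373, 0.16885540],
            [0.15432897, 0.53532814, 0.44463454]),
    ],
    "C": [
        (0, [71.6168370, 13.0450960, 3.5305122],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [2.9412494, 0.6834831, 0.2222899],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [2.9412494, 0.6834831, 0.2222899],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
    "N": [
        (0, [99.1061690, 18.0523120, 4.8856602],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [3.7804559, 0.8784966, 0.2857144],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [3.7804559, 0.8784966, 0.2857144],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
    "O": [
        (0, [130.7093200, 23.8088610, 6.4436083],
            [0.15432897, 0.53532814, 0.44463454]),
        (0, [5.0331513, 1.1695961, 0.3803890],
            [-0.09996723, 0.39951283, 0.70011547]),
        (1, [5.0331513, 1.1695961, 0.3803890],
            [0.15591627, 0.60768372, 0.39195739]),
    ],
}

_CCPVDZ = {
    "H": [
        (0, [13.0100, 1.9620, 0.4446, 0.1220],
            [0.0196850, 0.1379770, 0.4781480, 0.5012400]),
        (0, [0.1220], [1.0]),
        (1, [0.7270], [1.0]),
    ],
    "C": [
        (0, [6665.0, 1000.0, 228.0, 64.71, 21.06, 6.459, 2.343, 0.5361, 0.1596],
            [0.000692, 0.005329, 0.027077, 0.101718, 0.274740, 0.448564,
             0.285074, 0.015204, -0.003191]),
        (0, [6665.0, 1000.0, 228.0, 64.71, 21.06, 6.459, 2.343, 0.5361, 0.1596],
            [-0.000146, -0.001154, -0.005725, -0.023312, -0.063955, -0.149981,
             -0.127262, 0.544529, 0.580496]),
        (0, [0.1596], [1.0]),
        (1, [9.439, 2.002, 0.5456, 0.1517],
            [0.038109, 0.209480, 0.508557, 0.468842]),
        (1, [0.1517], [1.0]),
        (2, [0.5500], [1.0]),
    ],
    "N": [
        (0, [9046.0, 1357.0, 309.3, 87.73, 28.56, 10.21, 3.838, 0.7466, 0.2248],
            [0.000700, 0.005389, 0.027406, 0.103207, 0.278723, 0.448540,
             0.278238, 0.015440, -0.002864]),
        (0, [9046.0, 1357.0, 309.3, 87.73, 28.56, 10.21, 3.838, 0.7466, 0.2248],
            [-0.000153, -0.001208, -0.005992, -0.024544, -0.067459, -0.158078,
             -0.121831, 0.549003, 0.578815]),
        (0, [0.2248], [1.0]),
        (1, [13.55, 2.917, 0.7973, 0.2185],
            [0.039919, 0.217169, 0.510319, 0.462313]),
        (1, [0.2185], [1.0]),
        (2, [0.8170], [1.0]),
    ],
    "O": [
        (0, [11720.0, 1759.0, 400.8, 113.7, 37.03, 13.27, 5.025, 1.013, 0.3023],
            [0.000710, 0.005470, 0.027837, 0.104800, 0.283062, 0.448719,
             0.270952, 0.015458, -0.002585]),
        (0, [11720.0, 1759.0, 400.8, 113.7, 37.03, 13.27, 5.025, 1.013, 0.3023],
            [-0.000160, -0.001263, -0.006267, -0.025716, -0.070924, -0.165411,
             -0.116955, 0.557368, 0.572759]),
        (0, [0.3023], [1.0]),
        (1, [17.70, 3.854, 1.046, 0.2753],
            [0.043018, 0.228913, 0.508728, 0.460531]),
        (1, [0.2753], [1.0]),
        (2, [1.1850], [1.0]),
    ],
}

BASIS_SETS = {"sto-3g": _STO3G, "cc-pvdz": _CCPVDZ}


class BasisError(ValueError):
    """Unsupported basis label or element/basis combination."""


@dataclass
class Shell:
    l: int
    exps: np.ndarray
    coefs: np.ndarray
    center: np.ndarray  # bohr
    atom: int

    @property
    def ncart(self) -> int:
        return (self.l + 1) * (self.l + 2) // 2


def cartesian_components(l: int) -> list[tuple[int, int, int]]:
    """Cartesian powers for angular momentum l, lexicographic order."""
    out = []
    for lx in range(l, -1, -1):
        for ly in range(l - lx, -1, -1):
            out.append((lx, ly, l - lx - ly))
    return out


def build_shells(system: MolecularSystem) -> tuple[list[Shell], np.ndarray]:
    """Build the shell list and the AO->atom map for a molecular system."""
    shells: list[Shell] = []
    ao_atoms: list[int] = []
    for iatom, sym in enumerate(system.atoms):
        label = system.basis_of(iatom).lower()
        if label not in BASIS_SETS:
            raise BasisError(f"unsupported basis set {label!r}")
        table = BASIS_SETS[label]
        if sym not in table:
            raise BasisError(f"element {sym} not available in basis {label!r}")
        center = system.coords[iatom] * ANGSTROM_TO_BOHR
        for l, exps, coefs in table[sym]:
            sh = Shell(
                l=l,
                exps=np.asarray(exps, dtype=float),
                coefs=np.asarray(coefs, dtype=float),
                center=np.asarray(center, dtype=float),
                atom=iatom,
            )
            shells.append(sh)
            ao_atoms += [iatom] * sh.ncart
    return shells, np.array(ao_atoms, dtype=np.int64)


def n_ao(system: MolecularSystem) -> int:
    shells, _ = build_shells(system)
    return sum(s.ncart for s in shells)
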