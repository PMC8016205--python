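"""Molecular systems: geometry ingestion, active-region selection, fixtures.

Coordinates are stored in Angstrom throughout; conversion to bohr happens
only inside the integral layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

ANGSTROM_TO_BOHR = 1.8897259886

ELEMENTS = {
    "H": 1, "He": 2, "Li": 3, "Be": 4, "B": 5, "C": 6, "N": 7, "O": 8,
    "F": 9, "Ne": 10, "Na": 11, "Mg": 12, "Al": 13, "Si": 14, "P": 15,
    "S": 16, "Cl": 17, "Ar": 18,
}

#: number of chemical-core orbitals kept frozen per element
CORE_ORBITALS = {z: 0 if z <= 2 else (1 if z <= 10 else 5) for z in range(1, 19)}


class XYZParseError(ValueError):
    """Raised for malformed XYZ input; the message names the offending line."""


@dataclass
class MolecularSystem:
    """A molecule with optional nested active-region levels.

    ``region_levels`` is an ordered list of atom-index sets, outermost first
    (HF-active ⊇ MLCC-active ⊇ higher-level-CC-active). Each level must be a
    subset of the previous one.
    """

    atoms: list[str]
    coords: np.ndarray  # (n_atoms, 3), Angstrom
    charge: int = 0
    basis: str | list[str] = "sto-3g"
    region_levels: list[set[int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(len(self.atoms), 3)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        for sym in self.atoms:
            if sym not in ELEMENTS:
                raise ValueError(f"unknown element {sym!r}")
        if self.n_electrons % 2 != 0:
            raise ValueError(
                f"open-shell systems are not supported "
                f"({self.n_electrons} electrons with charge {self.charge})"
            )
        prev: set[int] | None = None
        for level in self.region_levels:
            if any(i < 0 or i >= len(self.atoms) for i in level):
                raise ValueError("region level references a nonexistent atom")
            if prev is not None and not level <= prev:
                raise ValueError("region levels must be nested")
            prev = set(level)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def charges(self) -> np.ndarray:
        return np.array([ELEMENTS[a] for a in self.atoms], dtype=float)

    @property
    def n_electrons(self) -> int:
        return int(sum(ELEMENTS[a] for a in self.atoms)) - self.charge

    def basis_of(self, iatom: int) -> str:
        if isinstance(self.basis, str):
            return self.basis
        return self.basis[iatom]

    def nuclear_repulsion(self) -> float:
        """Nuclear repulsion energy in hartree."""
        z = self.charges
        r = self.coords * ANGSTROM_TO_BOHR
        e = 0.0
        for i in range(self.n_atoms):
            for j in range(i + 1, self.n_atoms):
                e += z[i] * z[j] / np.linalg.norm(r[i] - r[j])
        return e

    def subsystem(self, atom_indices) -> "MolecularSystem":
        idx = sorted(atom_indices)
        basis = self.basis if isinstance(self.basis, str) else [self.basis[i] for i in idx]
        return MolecularSystem(
            atoms=[self.atoms[i] for i in idx],
            coords=self.coords[idx],
            charge=0,
            basis=basis,
        )

    def to_xyz(self, comment: str = "") -> str:
        lines = [str(self.n_atoms), comment]
        for sym, (x, y, z) in zip(self.atoms, self.coords):
            lines.append(f"{sym:<3s} {x: 20.12f} {y: 20.12f} {z: 20.12f}")
        return "\n".join(lines) + "\n"


def parse_xyz(text: str, charge: int = 0, basis: str = "sto-3g") -> MolecularSystem:
    """Parse a standard two-header-line XYZ block (coordinates in Angstrom)."""
    lines = text.splitlines()
    if not lines:
        raise XYZParseError("empty XYZ input (line 1)")
    try:
        natoms = int(lines[0].split()[0])
    except (IndexError, ValueError) as exc:
        raise XYZParseError(f"malformed atom-count header (line 1): {lines[0]!r}") from exc
    if natoms <= 0:
        raise XYZParseError("XYZ header declares no atoms (line 1)")
    body = lines[2 : 2 + natoms]
    if len(body) < natoms:
        raise XYZParseError(
            f"header declares {natoms} atoms but only {len(body)} atom lines found"
        )
    atoms: list[str] = []
    coords: list[list[float]] = []
    for k, line in enumerate(body, start=3):
        parts = line.split()
        if len(parts) < 4:
            raise XYZParseError(f"malformed atom line (line {k}): {line!r}")
        sym = parts[0].capitalize()
        if sym not in ELEMENTS:
            raise XYZParseError(f"unknown element {parts[0]!r} (line {k})")
        try:
            coords.append([float(p) for p in parts[1:4]])
        except ValueError as exc:
            raise XYZParseError(f"bad coordinate (line {k}): {line!r}") from exc
        atoms.append(sym)
    return MolecularSystem(atoms=atoms, coords=np.array(coords), charge=charge, basis=basis)


def select_region_by_radius(
    system: MolecularSystem,
    center_atoms,
    radius: float,
    keep_molecules: bool = True,
) -> set[int]:
    """Atoms whose nuclei lie within ``radius`` (Angstrom) of any center atom.

    With ``keep_molecules`` (the default) whole solvent molecules are kept or
    dropped atomically: the system is partitioned into connected fragments by
    a covalent-distance criterion and a fragment is selected if any of its
    atoms is within the radius.  This avoids dangling bonds when carving
    solvation shells.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    center_atoms = sorted(set(int(i) for i in center_atoms))
    if not center_atoms:
        raise ValueError("no center atoms given")
    for i in center_atoms:
        if i < 0 or i >= system.n_atoms:
            raise ValueError(f"center atom {i} does not exist")
    d = np.linalg.norm(
        system.coords[:, None, :] - system.coords[None, center_atoms, :], axis=-1
    ).min(axis=1)
    selected = set(np.nonzero(d <= radius)[0].tolist()) | set(center_atoms)
    if keep_molecules:
        frags = molecular_fragments(system)
        out: set[int] = set()
        for frag in frags:
            if frag & selected:
                out |= frag
        selected = out
    if not selected - set(center_atoms):
        import warnings

        warnings.warn("radius selection returned only the center atoms", stacklevel=2)
    return selected


def molecular_fragments(system: MolecularSystem) -> list[set[int]]:
    """Connected fragments under a simple covalent-distance bond criterion."""
    n = system.n_atoms
    coords = system.coords
    # covalent radii (Angstrom), generous 1.2x tolerance below
    rcov = {"H": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "S": 1.05, "Cl": 1.02}
    radii = np.array([rcov.get(a, 1.0) for a in system.atoms])
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if np.linalg.norm(coords[i] - coords[j]) <= 1.2 * (radii[i] + radii[j]):
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pi] = pj
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


# --- embedded fixture geometries (Angstrom) -------------------------------

WATER_XYZ = """3
water, equilibrium-like geometry
O   0.0000000   0.0000000   0.1173000
H   0.0000000   0.7572000  -0.4692000
H   0.0000000  -0.7572000  -0.4692000
"""

FORMALDEHYDE_XYZ = """4
formaldehyde
C   0.0000000   0.0000000   0.0000000
O   0.0000000   0.0000000   1.2050000
H   0.0000000   0.9429000  -0.5876000
H   0.0000000  -0.9429000  -0.5876000
"""

ETHENE_XYZ = """6
ethene
C   0.0000000   0.0000000   0.6695000
C   0.0000000   0.0000000  -0.6695000
H   0.0000000   0.9289000   1.2321000
H   0.0000000  -0.9289000   1.2321000
H   0.0000000   0.9289000  -1.2321000
H   0.0000000  -0.9289000  -1.2321000
"""

# planar model geometry of para-nitroaniline (ring along z, substituents on z axis)
PARA_NITROANILINE_XYZ = """16
para-nitroaniline, idealized planar model geometry
C   0.0000000   0.0000000   1.4150000
C   0.0000000   1.2045000   0.7195000
C   0.0000000   1.2045000  -0.6755000
C   0.0000000   0.0000000  -1.3960000
C   0.0000000  -1.2045000  -0.6755000
C   0.0000000  -1.2045000   0.7195000
H   0.0000000   2.1500000   1.2600000
H   0.0000000   2.1500000  -1.2160000
H   0.0000000  -2.1500000  -1.2160000
H   0.0000000  -2.1500000   1.2600000
N   0.0000000   0.0000000   2.7950000
H   0.0000000   0.8300000   3.3490000
H   0.0000000  -0.8300000   3.3490000
N   0.0000000   0.0000000  -2.8560000
O   0.0000000   1.0850000  -3.4540000
O   0.0000000  -1.0850000  -3.4540000
"""


def water(basis: str = "sto-3g") -> MolecularSystem:
    return parse_xyz(WATER_XYZ, basis=basis)


def formaldehyde(basis: str = "sto-3g") -> MolecularSystem:
    return parse_xyz(FORMALDEHYDE_XYZ, basis=basis)


def ethene(basis: str = "sto-3g") -> MolecularSystem:
    return parse_xyz(ETHENE_XYZ, basis=basis)


def para_nitroaniline(basis: str = "sto-3g") -> MolecularSystem:
    return parse_xyz(PARA_NITROANILINE_XYZ, basis=basis)


_WATER_FRAME = np.array(
    [[0.0, 0.0, 0.1173], [0.0, 0.7572, -0.4692], [0.0, -0.7572, -0.4692]]
)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random rotation matrix via QR of a Gaussian matrix."""
    m = rng.standard_normal((3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def generate_solvated_fixture(
    n_waters: int,
    seed: int,
    solute: MolecularSystem | None = None,
    clash: float = 1.5,
    shell_width: float = 2.2,
    max_retries: int = 2000,
) -> MolecularSystem:
    """Pack ``n_waters`` rigid water molecules in a shell around ``solute``.

    Deterministic for a fixed seed.  No two atoms end up closer than
    ``clash`` Angstrom (verified by construction).  Emulates a solute in an
    explicit solvation shell at desk scale.
    """
    if n_waters < 0:
        raise ValueError("n_waters must be >= 0")
    if solute is None:
        solute = water()
    if n_waters == 0:
        return MolecularSystem(
            atoms=list(solute.atoms),
            coords=solute.coords.copy(),
            charge=solute.charge,
            basis=solute.basis,
        )
    rng = np.random.default_rng(seed)
    atoms = list(solute.atoms)
    coords = [solute.coords.copy()]
    placed = solute.coords.copy()
    center = solute.coords.mean(axis=0)
    r0 = np.max(np.linalg.norm(solute.coords - center, axis=1)) + 2.4
    shell_outer = r0 + shell_width
    n_placed = 0
    for attempt in range(max_retries):
        if n_placed == n_waters:
            break
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        radius = r0 + (shell_outer - r0) * rng.random()
        origin = center + radius * direction
        frame = _WATER_FRAME @ _random_rotation(rng).T + origin
        dmin = np.min(
            np.linalg.norm(placed[:, None, :] - frame[None, :, :], axis=-1)
        )
        if dmin < clash:
            # grow the shell slowly if packing gets tight
            shell_outer += 0.02
            continue
        atoms += ["O", "H", "H"]
        coords.append(frame)
        placed = np.vstack([placed, frame])
        n_placed += 1
    if n_placed < n_waters:
        raise RuntimeError(
            f"failed to pack {n_waters} waters after {max_retries} tries (seed={seed})"
        )
    return MolecularSystem(
        atoms=atoms, coords=np.vstack(coords), charge=solute.charge, basis=solute.basis
    )
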