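"""End-to-end orchestration: reference -> (reduced space) -> partition ->
Cholesky ERI -> MLCC -> excited states, with machine-readable reporting.

Defaults follow the package's standard thresholds: SCF gradient 1e-8,
Cholesky threshold 1e-3 (1e-4 with MO screening), ground-state residual
1e-6, excited-state residual 1e-4, occupied-Cholesky pivot threshold 1e-2,
frozen core on.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import mlcc2, mlccsd
from .cholesky import (DEFAULT_TAU_SCREENED, DEFAULT_TAU_UNSCREENED, decompose)
from .dressing import HARTREE_TO_EV
from .integrals import compute_ao_integrals
from .orbitals import (approximate_doubles, build_cnto_matrices,
                       ccs_excitation_vectors, cholesky_occupied_orbitals,
                       construct_paos, empty_partition, full_partition,
                       partition_from_regions, _retained_canonical,
                       select_active_space, semicanonicalize)
from .scf import freeze_core, freeze_occupied, run_rhf
from .system import MolecularSystem, molecular_fragments, select_region_by_radius

METHODS = ("ccs", "cc2", "ccsd", "mlcc2", "mlccsd")
SCHEMES = ("cnto", "cholesky-pao")


class StageError(RuntimeError):
    def __init__(self, stage: str, original: Exception):
        super().__init__(f"stage {stage!r} failed: {original}")
        self.stage = stage


@dataclass
class RunConfig:
    """Calculation configuration; every field is mirrored by a CLI flag."""

    method: str = "mlcc2"
    basis: str = "sto-3g"
    basis_cc: str | None = None  # larger basis on CC-region atoms
    charge: int = 0
    n_states: int = 1
    scheme: str = "cnto"
    active_occ: int | None = None
    active_virt: int | None = None  # None with active_occ set -> ratio rule
    r_cc: float | None = None  # reduced-space (MLCC-in-HF) radius, Angstrom
    r_cc2: float | None = None  # higher-level region radius (cholesky-pao)
    r_ccsd: float | None = None  # alias for r_cc2 with method mlccsd
    frozen_core: bool = True
    scf_tol: float = 1e-8
    cd_tau: float | None = None  # default: 1e-3, or 1e-4 when screened
    cd_screen: bool | None = None  # default: screen iff reduced space
    gs_tol: float = 1e-6
    es_tol: float = 1e-4
    pivot_tol: float = 1e-2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}")

    @classmethod
    def from_mapping(cls, data: dict) -> "RunConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _solute_atoms(system: MolecularSystem) -> set[int]:
    """The largest non-water fragment, or the first fragment as fallback."""
    frags = molecular_fragments(system)
    non_water = [f for f in frags
                 if sorted(system.atoms[i] for i in f) != ["H", "H", "O"]]
    pool = non_water if non_water else frags
    return max(pool, key=len)


def run(config: RunConfig, system: MolecularSystem) -> dict:
    """Execute the configured workflow; returns a machine-readable report.

    All displayed tables can be regenerated from this report; energies are
    reported in hartree and eV (conversion constant in the header).
    """
    report: dict = {
        "version": 1,
        "ev_per_hartree": HARTREE_TO_EV,
        "config": asdict(config),
        "n_atoms": system.n_atoms,
    }
    method = config.method
    base = "cc2" if method in ("ccs", "cc2", "mlcc2") else "ccsd"
    screen = config.cd_screen
    if screen is None:
        screen = config.r_cc is not None
    tau = config.cd_tau
    if tau is None:
        tau = DEFAULT_TAU_SCREENED if screen else DEFAULT_TAU_UNSCREENED

    stage = "integrals"
    try:
        if config.basis_cc is not None and config.r_cc is not None:
            cc_atoms = select_region_by_radius(
                system, _solute_atoms(system), config.r_cc
            )
            basis = [config.basis_cc if i in cc_atoms else config.basis
                     for i in range(system.n_atoms)]
            system = MolecularSystem(system.atoms, system.coords,
                                     charge=config.charge, basis=basis)
        elif system.basis_of(0) != config.basis and isinstance(system.basis, str):
            system = MolecularSystem(system.atoms, system.coords,
                                     charge=config.charge, basis=config.basis)
        ints = compute_ao_integrals(system)
        report["n_ao"] = ints.n_ao

        stage = "scf"
        ref = run_rhf(ints, system, gradient_tol=config.scf_tol)
        report["scf_energy"] = ref.energy
        if config.frozen_core:
            ref = freeze_core(ref, system)
        report["n_frozen_core"] = ref.n_frozen

        stage = "reduced_space"
        region_levels: list[set[int]] = []
        if config.r_cc is not None:
            solute = _solute_atoms(system)
            cc_atoms = select_region_by_radius(system, solute, config.r_cc)
            region_levels.append(cc_atoms)
            C, eps, no_r, nv_r = _retained_canonical(ref)
            Co, Cv = C[:, :no_r], C[:, no_r:]
            D = Co @ Co.T
            C_oa, C_oi = cholesky_occupied_orbitals(
                D, ints.S, _atom_aos(ints, cc_atoms), Co, config.pivot_tol
            )
            C_va, _ = construct_paos(
                D, ints.S, _atom_aos(ints, cc_atoms), 1e-6, C_virt_span=Cv
            )
            frozen = np.hstack([ref.C[:, : ref.n_frozen], C_oi]) \
                if ref.n_frozen else C_oi
            ref = freeze_occupied(ref, frozen, C_oa, C_va)
        report["n_mo"] = ref.n_occ_active + ref.n_virt
        report["n_occ"] = ref.n_occ_active
        report["n_virt"] = ref.n_virt

        stage = "partition"
        if method in ("cc2", "ccsd"):
            partition = full_partition(ref)
        elif method == "ccs":
            partition = empty_partition(ref)
        elif config.scheme == "cnto":
            partition = _cnto_partition(ref, config)
        else:
            r_high = config.r_cc2 if config.r_cc2 is not None else config.r_ccsd
            if r_high is None:
                raise ValueError("cholesky-pao scheme needs r_cc2/r_ccsd")
            high_atoms = select_region_by_radius(
                system, _solute_atoms(system), r_high
            )
            if region_levels and not high_atoms <= region_levels[-1]:
                high_atoms &= region_levels[-1]
            region_levels.append(high_atoms)
            partition = partition_from_regions(
                ref, _atom_aos(ints, high_atoms), pivot_tol=config.pivot_tol
            )
        partition = semicanonicalize(ref.F_ao, partition)
        report["n_occ_active"] = partition.n_occ_active
        report["n_virt_active"] = partition.n_virt_active
        report["orbital_scheme"] = partition.provenance
        report["region_levels"] = [sorted(r) for r in region_levels]

        stage = "cholesky_eri"
        cderi = decompose(
            ints, partition.C, tau=tau, screen=screen,
            C_active=partition.C if screen else None,
        )
        report["cd_tau"] = tau
        report["cd_screen"] = bool(screen)
        report["n_cholesky_vectors"] = cderi.n_vectors

        stage = "ground_state"
        module = mlcc2 if base == "cc2" else mlccsd
        gs = module.ground_state(ref, partition, cderi, tol=config.gs_tol)
        report["total_energy"] = gs.energy
        report["correlation_energy"] = gs.correlation_energy
        report["gs_iterations"] = gs.info["iterations"]
        report["gs_residual_norms"] = list(gs.info["residual_norms"])

        stage = "excited_states"
        if config.n_states > 0:
            states = module.excited_states(
                gs, config.n_states, tol=config.es_tol, seed=config.seed
            )
            report["omega_hartree"] = [w for w, _ in states]
            report["omega_ev"] = [w * HARTREE_TO_EV for w, _ in states]
        else:
            report["omega_hartree"] = []
            report["omega_ev"] = []
    except Exception as exc:  # noqa: BLE001 - stage attribution
        raise StageError(stage, exc) from exc
    return report


def _atom_aos(ints, atoms) -> list[int]:
    return [i for i, a in enumerate(ints.ao_atoms) if a in atoms]


def _cnto_partition(ref, config: RunConfig):
    if config.active_occ is None:
        raise ValueError("cnto scheme needs active_occ (and optionally active_virt)")
    cis = ccs_excitation_vectors(ref, max(config.n_states, 1), seed=config.seed)
    C, eps, no, nv = _retained_canonical(ref)
    g_mo = np.einsum(
        "abcd,ap,bq,cr,ds->pqrs", ref.ints.g, C, C, C, C, optimize=True
    )
    states = []
    for w, R1 in cis:
        R2 = approximate_doubles(R1, w, eps[:no], eps[no:], g_mo=g_mo)
        states.append((R1, R2))
    dens = build_cnto_matrices(states)
    return select_active_space(
        dens, C[:, :no], C[:, no:], config.active_occ, config.active_virt
    )


def compare_runs(reports: list[dict]) -> dict:
    """Convergence table of omega vs active-space size across runs.

    Deltas are relative to the run with the largest active space.
    """
    if not reports:
        raise ValueError("no reports given")
    key0 = (reports[0]["n_atoms"], reports[0]["config"]["basis"])
    for r in reports:
        if (r["n_atoms"], r["config"]["basis"]) != key0:
            raise ValueError("reports stem from different systems")
    ordered = sorted(
        reports, key=lambda r: (r["n_occ_active"] + r["n_virt_active"])
    )
    ref = ordered[-1]
    rows = []
    for r in ordered:
        deltas = [
            (w - wr) * HARTREE_TO_EV
            for w, wr in zip(r["omega_hartree"], ref["omega_hartree"])
        ]
        rows.append({
            "method": r["config"]["method"],
            "n_occ_active": r["n_occ_active"],
            "n_virt_active": r["n_virt_active"],
            "omega_ev": r["omega_ev"],
            "delta_ev": deltas,
        })
    return {"reference": ref["config"]["method"], "rows": rows}


def format_table(table: dict) -> str:
    lines = [f"{'method':>8s} {'n_o^a':>6s} {'n_v^a':>6s}  omega [eV]  delta [eV]"]
    for row in table["rows"]:
        om = " ".join(f"{w:8.4f}" for w in row["omega_ev"])
        dl = " ".join(f"{d:+8.4f}" for d in row["delta_ev"])
        lines.append(
            f"{row['method']:>8s} {row['n_occ_active']:6d} "
            f"{row['n_virt_active']:6d}  {om}  {dl}"
        )
    return "\n".join(lines)


def save_report(report: dict, path: str) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)


def load_report(path: str) -> dict:
    with open(path) as fh:
        return json.load(fh)
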