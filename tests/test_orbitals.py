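"""Active-space construction: Cholesky orbitals, PAOs, CNTOs, semicanonical."""

import numpy as np
import pytest
import scipy.linalg as sla

from conftest import mo_eri
from mlccx.orbitals import (CNTODensities, _retained_canonical,
                            approximate_doubles, build_cnto_matrices,
                            ccs_excitation_vectors, cholesky_occupied_orbitals,
                            construct_paos, empty_partition, full_partition,
                            ratio_rule_virtuals, select_active_space,
                            semicanonicalize)


def occ_projector(S, C):
    return C @ C.T @ S


class TestCholeskyOccupied:
    def test_all_aos_active_spans_occupied_space(self, water_sto3g):
        _, ints, ref = water_sto3g
        Co = ref.C[:, : ref.n_occ]
        D = Co @ Co.T
        C_act, C_in = cholesky_occupied_orbitals(
            D, ints.S, range(ints.n_ao), Co, pivot_tol=1e-12
        )
        assert C_act.shape[1] == ref.n_occ
        assert C_in.shape[1] == 0
        P = occ_projector(ints.S, C_act)
        assert np.max(np.abs(P - occ_projector(ints.S, Co))) < 1e-8

    def test_no_active_aos_gives_no_active_orbitals(self, water_sto3g):
        _, ints, ref = water_sto3g
        Co = ref.C[:, : ref.n_occ]
        C_act, C_in = cholesky_occupied_orbitals(Co @ Co.T, ints.S, [], Co)
        assert C_act.shape[1] == 0
        assert C_in.shape[1] == ref.n_occ

    def test_matches_dense_pivoted_cholesky_oracle(self, shell5):
        """Active span equals a brute-force restricted Cholesky of D."""
        _, ints, ref = shell5
        Co = ref.C[:, : ref.n_occ]
        D = Co @ Co.T
        active_aos = [i for i, a in enumerate(ints.ao_atoms) if a < 3]
        C_act, C_in = cholesky_occupied_orbitals(D, ints.S, active_aos, Co,
                                                 pivot_tol=1e-2)
        # oracle: same greedy decomposition written against the full matrix
        R = D.copy()
        vecs = []
        while True:
            d = np.diag(R)[active_aos]
            k = int(np.argmax(d))
            if d[k] <= 1e-2:
                break
            piv = active_aos[k]
            ell = R[:, piv] / np.sqrt(R[piv, piv])
            vecs.append(ell)
            R -= np.outer(ell, ell)
        X = np.column_stack(vecs)
        O = X.T @ ints.S @ X
        lam, V = sla.eigh(O)
        C_oracle = X @ V[:, lam > 1e-10] / np.sqrt(lam[lam > 1e-10])
        assert C_act.shape[1] == C_oracle.shape[1]
        P1 = occ_projector(ints.S, C_act)
        P2 = occ_projector(ints.S, C_oracle)
        assert np.max(np.abs(P1 - P2)) < 1e-8
        # active + inactive together span the occupied space
        both = np.hstack([C_act, C_in])
        assert np.max(np.abs(occ_projector(ints.S, both)
                             - occ_projector(ints.S, Co))) < 1e-8
        assert np.allclose(both.T @ ints.S @ both,
                           np.eye(both.shape[1]), atol=1e-8)


class TestPAOs:
    def test_all_atoms_active_spans_virtual_space(self, water_sto3g):
        _, ints, ref = water_sto3g
        Co = ref.C[:, : ref.n_occ]
        D = Co @ Co.T
        C_va, C_vi = construct_paos(D, ints.S, range(ints.n_ao), 1e-8)
        assert C_va.shape[1] == ints.n_ao - ref.n_occ
        assert C_vi.shape[1] == 0
        assert np.max(np.abs(Co.T @ ints.S @ C_va)) < 1e-10

    def test_occupied_pao_overlap_vanishes_for_any_active_set(self, shell5):
        _, ints, ref = shell5
        Co = ref.C[:, : ref.n_occ]
        D = Co @ Co.T
        active_aos = [i for i, a in enumerate(ints.ao_atoms) if a < 6]
        C_va, C_vi = construct_paos(D, ints.S, active_aos, 1e-6)
        assert np.max(np.abs(Co.T @ ints.S @ C_va)) < 1e-9
        assert np.max(np.abs(Co.T @ ints.S @ C_vi)) < 1e-9

    def test_virtual_projectors_resolve_identity(self, shell5):
        """Active + inactive virtual projectors equal 1 - P_occ."""
        _, ints, ref = shell5
        S = ints.S
        Co = ref.C[:, : ref.n_occ]
        D = Co @ Co.T
        active_aos = [i for i, a in enumerate(ints.ao_atoms) if a < 3]
        C_va, C_vi = construct_paos(D, ints.S, active_aos, 1e-6)
        assert C_va.shape[1] + C_vi.shape[1] == ints.n_ao - ref.n_occ
        P = occ_projector(S, C_va) + occ_projector(S, C_vi)
        assert np.max(np.abs(P - (np.eye(ints.n_ao) - D @ S))) < 1e-8

    def test_empty_active_set_rejected(self, water_sto3g):
        _, ints, ref = water_sto3g
        Co = ref.C[:, : ref.n_occ]
        with pytest.raises(ValueError):
            construct_paos(Co @ Co.T, ints.S, [], 1e-6)


class TestCCSVectors:
    def test_matches_dense_cis_diagonalization(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 3)
        # independent dense CIS construction
        C, eps, no, nv = _retained_canonical(ref)
        g = mo_eri(ints.g, C)
        A = np.zeros((no * nv, no * nv))
        for i in range(no):
            for a in range(nv):
                for j in range(no):
                    for b in range(nv):
                        v = 2 * g[i, no + a, j, no + b] - g[i, j, no + a, no + b]
                        if i == j and a == b:
                            v += eps[no + a] - eps[i]
                        A[i * nv + a, j * nv + b] = v
        w = np.sort(sla.eigvalsh(0.5 * (A + A.T)))
        for k, (omega, R) in enumerate(states):
            assert omega == pytest.approx(w[k], abs=1e-8)
            assert np.linalg.norm(R) == pytest.approx(1.0, abs=1e-10)

    def test_excitation_energies_positive(self, water_sto3g_fc):
        _, _, ref = water_sto3g_fc
        assert all(w > 0 for w, _ in ccs_excitation_vectors(ref, 4))

    def test_degenerate_states_orthonormal(self, water_dz_fc):
        _, _, ref = water_dz_fc
        states = ccs_excitation_vectors(ref, 4)
        for i in range(len(states)):
            for j in range(i):
                dot = np.sum(states[i][1] * states[j][1])
                assert abs(dot) < 1e-8


class TestApproximateDoubles:
    def test_zero_singles_give_zero_doubles(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        C, eps, no, nv = _retained_canonical(ref)
        g = mo_eri(ints.g, C)
        R2 = approximate_doubles(np.zeros((no, nv)), 0.3, eps[:no], eps[no:],
                                 g_mo=g)
        assert np.all(R2 == 0)

    def test_pair_exchange_symmetry(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 2)
        C, eps, no, nv = _retained_canonical(ref)
        g = mo_eri(ints.g, C)
        for w, R1 in states:
            R2 = approximate_doubles(R1, w, eps[:no], eps[no:], g_mo=g)
            assert np.max(np.abs(R2 - R2.transpose(2, 3, 0, 1))) < 1e-12

    def test_matches_explicit_loop_construction(self, water_sto3g_fc):
        """Einsum contraction equals a nested-loop reference implementation."""
        _, ints, ref = water_sto3g_fc
        (w, R1), = ccs_excitation_vectors(ref, 1)
        C, eps, no, nv = _retained_canonical(ref)
        g = mo_eri(ints.g, C)
        R2 = approximate_doubles(R1, w, eps[:no], eps[no:], g_mo=g)
        o = slice(0, no)
        for i in range(no):
            for a in range(nv):
                for j in range(no):
                    for b in range(nv):
                        bterm = 0.0
                        for k in range(no):
                            bterm -= R1[k, a] * g[k, i, no + b, j]
                            bterm -= R1[k, b] * g[no + a, i, k, j]
                        for c in range(nv):
                            bterm += R1[i, c] * g[no + a, no + c, no + b, j]
                            bterm += R1[j, c] * g[no + a, i, no + b, no + c]
                        denom = (eps[no + a] + eps[no + b]
                                 - eps[i] - eps[j] - w)
                        assert R2[i, a, j, b] == pytest.approx(
                            -bterm / denom, abs=1e-10
                        )


class TestCNTOMatrices:
    def test_rank_one_singles_select_that_orbital(self):
        R1 = np.zeros((4, 6))
        R1[2, 3] = 1.0
        dens = build_cnto_matrices([(R1, None)])
        lam, U = sla.eigh(dens.M)
        assert lam[-1] == pytest.approx(1.0)
        assert abs(U[2, -1]) == pytest.approx(1.0)
        assert np.linalg.matrix_rank(dens.M, tol=1e-12) == 1

    def test_matrices_psd_and_trace_identity(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 2)
        C, eps, no, nv = _retained_canonical(ref)
        g = mo_eri(ints.g, C)
        pairs = [(R1, approximate_doubles(R1, w, eps[:no], eps[no:], g_mo=g))
                 for w, R1 in states]
        dens = build_cnto_matrices(pairs)
        for M in (dens.M, dens.N):
            lam = sla.eigvalsh(M)
            assert lam.min() > -1e-12
            assert np.trace(M) == pytest.approx(np.sum(lam), abs=1e-12)

    def test_multi_state_additivity(self):
        rng = np.random.default_rng(0)
        R1a, R1b = rng.standard_normal((2, 3, 5))
        da = build_cnto_matrices([(R1a, None)])
        db = build_cnto_matrices([(R1b, None)])
        dsum = build_cnto_matrices([(R1a, None), (R1b, None)])
        assert np.allclose(dsum.M, da.M + db.M, atol=1e-14)
        assert np.allclose(dsum.N, da.N + db.N, atol=1e-14)


class TestSelection:
    def test_ratio_rule_full_fraction(self):
        assert ratio_rule_virtuals(4, 4, 20) == 20
        assert ratio_rule_virtuals(2, 4, 20) == 10
        assert ratio_rule_virtuals(1, 4, 6) == 2  # round half up: 1.5 -> 2

    def test_full_and_empty_partitions_valid(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        for part in (full_partition(ref), empty_partition(ref)):
            C = part.C
            assert np.allclose(C.T @ ints.S @ C, np.eye(part.n_mo), atol=1e-8)

    def test_empty_active_space_partition(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 1)
        dens = build_cnto_matrices([(states[0][1], None)])
        C, eps, no, nv = _retained_canonical(ref)
        part = select_active_space(dens, C[:, :no], C[:, no:], 0, 0)
        assert part.n_occ_active == 0 and part.n_virt_active == 0
        assert np.allclose(part.C.T @ ints.S @ part.C,
                           np.eye(part.n_mo), atol=1e-8)

    def test_eigenvalue_coverage_monotone(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 1)
        C, eps, no, nv = _retained_canonical(ref)
        g = mo_eri(ints.g, C)
        w, R1 = states[0]
        dens = build_cnto_matrices(
            [(R1, approximate_doubles(R1, w, eps[:no], eps[no:], g_mo=g))]
        )
        lam = np.sort(sla.eigvalsh(dens.M))[::-1]
        coverage = [np.sum(lam[:k]) / np.sum(lam) for k in range(no + 1)]
        assert all(b >= a - 1e-12 for a, b in zip(coverage, coverage[1:]))

    def test_out_of_range_counts_rejected(self, water_sto3g_fc):
        _, _, ref = water_sto3g_fc
        dens = CNTODensities(M=np.eye(4), N=np.eye(2))
        C, eps, no, nv = _retained_canonical(ref)
        with pytest.raises(ValueError):
            select_active_space(dens, C[:, :no], C[:, no:], no + 1)


class TestSemicanonicalize:
    def test_full_active_space_recovers_canonical(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        part = semicanonicalize(ref.F_ao, full_partition(ref))
        F = part.C.T @ ref.F_ao @ part.C
        assert np.max(np.abs(F - np.diag(np.diag(F)))) < 1e-8

    def test_projectors_preserved(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 1)
        dens = build_cnto_matrices([(states[0][1], None)])
        C, eps, no, nv = _retained_canonical(ref)
        part = select_active_space(dens, C[:, :no], C[:, no:], 2)
        semi = semicanonicalize(ref.F_ao, part)
        S = ints.S
        for sl_pre, sl_post in zip(part.block_slices(), semi.block_slices()):
            P_pre = occ_projector(S, part.C[:, sl_pre])
            P_post = occ_projector(S, semi.C[:, sl_post])
            assert np.max(np.abs(P_pre - P_post)) < 1e-10

    def test_block_eigenvalues_match_dense_solver(self, water_sto3g_fc):
        _, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 1)
        dens = build_cnto_matrices([(states[0][1], None)])
        C, eps, no, nv = _retained_canonical(ref)
        part = select_active_space(dens, C[:, :no], C[:, no:], 2)
        semi = semicanonicalize(ref.F_ao, part)
        for sl in part.block_slices():
            if sl.stop == sl.start:
                continue
            Fb = part.C[:, sl].T @ ref.F_ao @ part.C[:, sl]
            want = np.sort(sla.eigvalsh(0.5 * (Fb + Fb.T)))
            got = np.sort(semi.eps[sl])
            assert np.allclose(got, want, atol=1e-10)

    def test_active_blocks_diagonal_after_transform(self, water_dz_fc):
        _, ints, ref = water_dz_fc
        states = ccs_excitation_vectors(ref, 1)
        dens = build_cnto_matrices([(states[0][1], None)])
        C, eps, no, nv = _retained_canonical(ref)
        part = semicanonicalize(
            ref.F_ao, select_active_space(dens, C[:, :no], C[:, no:], 2)
        )
        F = part.C.T @ ref.F_ao @ part.C
        oa = part.occ_active_slice
        va = part.virt_active_slice
        for sl in (oa, va):
            blk = F[sl, sl]
            assert np.max(np.abs(blk - np.diag(np.diag(blk)))) < 1e-8


class TestExportAndPermutation:
    def test_partition_export_blocks(self, water_sto3g_fc):
        from mlccx.orbitals import export_partition

        _, _, ref = water_sto3g_fc
        part = full_partition(ref)
        out = export_partition(part)
        assert out["occ_active"].shape[1] == part.n_occ_active
        assert out["virt_inactive"].shape[1] == 0
        assert str(out["provenance"]) == "canonical"

    def test_pao_pipeline_invariant_under_atom_reordering(self):
        """PAO projectors agree after consistently permuting the AO basis."""
        from mlccx.integrals import compute_ao_integrals
        from mlccx.scf import run_rhf
        from mlccx.system import MolecularSystem, water

        w = water()
        perm_atoms = [2, 0, 1]  # H, O, H ordering
        w2 = MolecularSystem([w.atoms[i] for i in perm_atoms],
                             w.coords[perm_atoms])
        def pao_projector(system, active_atom):
            ints = compute_ao_integrals(system)
            ref = run_rhf(ints, system)
            Co = ref.C[:, : ref.n_occ]
            D = Co @ Co.T
            aos = [i for i, a in enumerate(ints.ao_atoms) if a == active_atom]
            C_va, _ = construct_paos(D, ints.S, aos, 1e-6)
            return C_va @ C_va.T, ints.ao_atoms

        P1, ao_atoms1 = pao_projector(w, 0)
        P2, ao_atoms2 = pao_projector(w2, 1)
        # AO index map: new AO k of atom perm_atoms[a] -> old AO of that atom
        new_of_old = np.empty(len(ao_atoms1), dtype=int)
        for old_atom in range(3):
            old_aos = np.nonzero(ao_atoms1 == old_atom)[0]
            new_aos = np.nonzero(ao_atoms2 == perm_atoms.index(old_atom))[0]
            new_of_old[old_aos] = new_aos
        P2_mapped = P2[np.ix_(new_of_old, new_of_old)]
        assert np.max(np.abs(P1 - P2_mapped)) < 1e-8
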