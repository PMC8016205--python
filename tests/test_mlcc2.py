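"""MLCC2: dressing, analytic doubles, ground state, Jacobian, excitations."""

import numpy as np
import pytest
import scipy.linalg as sla

import spinorbital_oracle as so
from conftest import mo_eri
from mlccx import mlcc2
from mlccx.cholesky import decompose, reconstruct_mo_integrals
from mlccx.dressing import (CCAmplitudes, PairPacking, correlation_energy,
                            make_cc_system, omega, solve_s2,
                            x1_transform_cholesky)
from mlccx.orbitals import (_retained_canonical, build_cnto_matrices,
                            ccs_excitation_vectors, empty_partition,
                            full_partition, select_active_space,
                            semicanonicalize)


@pytest.fixture(scope="module")
def water_cc(water_sto3g_fc):
    """Full-space CC setup plus matching spin-orbital oracle integrals."""
    system, ints, ref = water_sto3g_fc
    part = full_partition(ref)
    cd = decompose(ints, part.C, tau=1e-11)
    ccsys = make_cc_system(ref, part, cd)
    g_sp = mo_eri(ints.g, part.C)
    f_sp = part.C.T @ ref.F_ao @ part.C
    g_so, f_so = so.spin_orbital_integrals(g_sp, f_sp)
    return ref, part, cd, ccsys, g_sp, g_so, f_so


def random_amplitudes(ccsys, seed=0, scale=0.05):
    rng = np.random.default_rng(seed)
    no, nv = ccsys.n_occ, ccsys.n_virt
    noa, nva = ccsys.n_occ_active, ccsys.n_virt_active
    t1 = scale * rng.standard_normal((no, nv))
    t2 = scale * rng.standard_normal((noa, noa, nva, nva))
    t2 = 0.5 * (t2 + t2.transpose(1, 0, 3, 2))
    return CCAmplitudes(t1, t2)


class TestX1Transform:
    def test_zero_amplitudes_identity(self, water_cc):
        _, _, _, ccsys, *_ = water_cc
        Ld, hd, Fd = x1_transform_cholesky(ccsys, np.zeros((ccsys.n_occ,
                                                            ccsys.n_virt)))
        assert np.array_equal(Ld, ccsys.L)
        assert np.allclose(hd, ccsys.h, atol=1e-14)
        assert np.allclose(Fd, ccsys.F0, atol=1e-10)

    def test_dressing_inverse(self, water_cc):
        _, _, _, ccsys, *_ = water_cc
        t1 = random_amplitudes(ccsys, 1).t1
        Ld, _, _ = x1_transform_cholesky(ccsys, t1)
        sys2 = type(ccsys)(
            L=Ld, F0=ccsys.F0, h=ccsys.h, eps=ccsys.eps, n_occ=ccsys.n_occ,
            n_occ_active=ccsys.n_occ_active, n_virt_active=ccsys.n_virt_active,
            e_scf=ccsys.e_scf,
        )
        Lb, _, _ = x1_transform_cholesky(sys2, -t1)
        assert np.max(np.abs(Lb - ccsys.L)) < 1e-12

    def test_dressed_integrals_match_dense_similarity_transform(self, water_cc):
        """Factorized dressing equals dressing the dense 4-index tensor."""
        ref, part, cd, ccsys, g_sp, _, _ = water_cc
        t1 = random_amplitudes(ccsys, 2).t1
        Ld, _, _ = x1_transform_cholesky(ccsys, t1)
        g_fact = np.einsum("jpq,jrs->pqrs", Ld, Ld, optimize=True)
        n, no = ccsys.n_mo, ccsys.n_occ
        lam_l = np.eye(n)
        lam_l[no:, :no] -= t1.T
        lam_r = np.eye(n)
        lam_r[no:, :no] += t1.T
        g_chol = reconstruct_mo_integrals(cd)
        g_dense = np.einsum("pa,bq,rc,ds,abcd->pqrs", lam_l, lam_r,
                            lam_l, lam_r, g_chol, optimize=True)
        assert np.max(np.abs(g_fact - g_dense)) < 1e-9


class TestResidual:
    def test_matches_spin_orbital_oracle_at_random_amplitudes(self, water_cc):
        _, _, _, ccsys, _, g_so, f_so = water_cc
        for seed in (0, 1):
            amps = random_amplitudes(ccsys, seed)
            om1, om2 = omega(ccsys, amps, "cc2")
            t1_so, t2_so = so.embed_singlet(amps.t1, amps.t2)
            r1_so, r2_so = so.cc2_residual(f_so, g_so, 2 * ccsys.n_occ,
                                           t1_so, t2_so)
            r1, r2 = so.extract_rows(r1_so, r2_so)
            assert np.max(np.abs(om1 - r1)) < 1e-9
            assert np.max(np.abs(om2 - r2)) < 1e-9


class TestSolveS2:
    def test_empty_active_space(self, water_sto3g_fc):
        system, ints, ref = water_sto3g_fc
        part = empty_partition(ref)
        cd = decompose(ints, part.C, tau=1e-8)
        ccsys = make_cc_system(ref, part, cd)
        t2 = solve_s2(ccsys, np.zeros((ccsys.n_occ, ccsys.n_virt)))
        assert t2.size == 0

    def test_defining_equation_residual_vanishes(self, water_cc):
        _, _, _, ccsys, *_ = water_cc
        t1 = random_amplitudes(ccsys, 3).t1
        t2 = solve_s2(ccsys, t1)
        _, om2 = omega(ccsys, CCAmplitudes(t1, t2), "cc2")
        assert np.max(np.abs(om2)) < 1e-10

    def test_matches_mp2_loop_oracle_at_zero_singles(self, water_cc):
        _, part, cd, ccsys, g_sp, _, _ = water_cc
        t2 = solve_s2(ccsys, np.zeros((ccsys.n_occ, ccsys.n_virt)))
        no, nv = ccsys.n_occ, ccsys.n_virt
        eps = ccsys.eps
        for i in range(no):
            for j in range(no):
                for a in range(nv):
                    for b in range(nv):
                        want = -g_sp[no + a, i, no + b, j] / (
                            eps[no + a] + eps[no + b] - eps[i] - eps[j]
                        )
                        assert t2[i, j, a, b] == pytest.approx(want, abs=1e-8)


class TestGroundState:
    def test_ccs_limit_zero_correlation(self, water_sto3g_fc):
        system, ints, ref = water_sto3g_fc
        part = empty_partition(ref)
        cd = decompose(ints, part.C, tau=1e-9)
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-10)
        assert gs.correlation_energy == pytest.approx(0.0, abs=1e-12)
        assert np.linalg.norm(gs.amplitudes.t1) < 1e-10

    def test_full_space_matches_cc2_oracle(self, water_cc):
        ref, part, cd, ccsys, _, g_so, f_so = water_cc
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-9)
        t1o, t2o, _ = so.solve_ground(f_so, g_so, 2 * ccsys.n_occ,
                                      so.cc2_residual, tol=1e-10)
        e_oracle = so.ccsd_energy(f_so, g_so, 2 * ccsys.n_occ, t1o, t2o)
        assert gs.correlation_energy == pytest.approx(e_oracle, abs=1e-7)

    def test_energy_invariant_under_inactive_occupied_rotations(
            self, water_sto3g_fc):
        system, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 1)
        dens = build_cnto_matrices([(states[0][1], None)])
        C, eps, no, nv = _retained_canonical(ref)
        part = select_active_space(dens, C[:, :no], C[:, no:], 2, 1)
        energies = []
        for seed in (0, 5):
            p = part
            ni = p.n_occ_inactive
            rng = np.random.default_rng(seed)
            Q, _ = np.linalg.qr(rng.standard_normal((ni, ni)))
            Cr = p.C.copy()
            Cr[:, :ni] = Cr[:, :ni] @ Q
            p = type(p)(C=Cr, n_occ_inactive=ni,
                        n_occ_active=p.n_occ_active,
                        n_virt_active=p.n_virt_active,
                        n_virt_inactive=p.n_virt_inactive)
            p = semicanonicalize(ref.F_ao, p)
            cd = decompose(ints, p.C, tau=1e-10)
            gs = mlcc2.ground_state(ref, p, cd, tol=1e-9)
            energies.append(gs.energy)
        assert energies[0] == pytest.approx(energies[1], abs=1e-9)


class TestJacobian:
    def test_zero_vector_maps_to_zero(self, water_cc):
        ref, part, cd, ccsys, *_ = water_cc
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-8)
        pk = PairPacking(ccsys)
        out = mlcc2.jacobian_apply(gs.ccsys, gs.amplitudes,
                                   np.zeros(pk.size))
        assert np.max(np.abs(out)) == 0.0

    def test_matches_finite_difference_jacobian(self, water_sto3g_fc):
        """Dense Jacobian from matrix-free actions vs central differences."""
        system, ints, ref = water_sto3g_fc
        states = ccs_excitation_vectors(ref, 1)
        dens = build_cnto_matrices([(states[0][1], None)])
        C, eps, no, nv = _retained_canonical(ref)
        part = semicanonicalize(
            ref.F_ao, select_active_space(dens, C[:, :no], C[:, no:], 2, 1)
        )
        cd = decompose(ints, part.C, tau=1e-10)
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-9)
        ccsys = gs.ccsys
        pk = PairPacking(ccsys)
        from mlccx.dressing import residual_function

        f = residual_function(ccsys, "cc2", pk)
        x0 = pk.pack(gs.amplitudes)
        h = 1e-5
        n = pk.size
        A_fd = np.zeros((n, n))
        A_an = np.zeros((n, n))
        for k in range(n):
            e = np.zeros(n)
            e[k] = 1.0
            A_fd[:, k] = (f(x0 + h * e) - f(x0 - h * e)) / (2 * h)
            A_an[:, k] = mlcc2.jacobian_apply(ccsys, gs.amplitudes, e, pk)
        assert np.max(np.abs(A_an - A_fd)) < 1e-6

    def test_empty_active_space_gives_cis_action(self, water_sto3g_fc):
        system, ints, ref = water_sto3g_fc
        part = empty_partition(ref)
        cd = decompose(ints, part.C, tau=1e-10)
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-10)
        ccsys = gs.ccsys
        pk = PairPacking(ccsys)
        no, nv = ccsys.n_occ, ccsys.n_virt
        g = reconstruct_mo_integrals(decompose(ints, part.C, tau=1e-12))
        A_cis = np.zeros((no * nv, no * nv))
        for i in range(no):
            for a in range(nv):
                for j in range(no):
                    for b in range(nv):
                        v = 2 * g[no + a, i, j, no + b] - g[no + a, no + b, j, i]
                        if i == j and a == b:
                            v += ccsys.eps[no + a] - ccsys.eps[i]
                        A_cis[i * nv + a, j * nv + b] = v
        for k in range(no * nv):
            e = np.zeros(pk.size)
            e[k] = 1.0
            col = mlcc2.jacobian_apply(ccsys, gs.amplitudes, e, pk)
            assert np.max(np.abs(col - A_cis[:, k])) < 1e-8


class TestExcitedStates:
    def test_full_space_matches_cc2_oracle(self, water_cc):
        ref, part, cd, ccsys, _, g_so, f_so = water_cc
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-9)
        states = mlcc2.excited_states(gs, 3, tol=1e-7, seed=0)
        t1o, t2o, _ = so.solve_ground(f_so, g_so, 2 * ccsys.n_occ,
                                      so.cc2_residual, tol=1e-10)
        w_oracle = so.oracle_excitations(f_so, g_so, 2 * ccsys.n_occ,
                                         so.cc2_residual, t1o, t2o, 3,
                                         tol=1e-7)
        for (w, _), wo in zip(states, w_oracle):
            assert w == pytest.approx(wo, abs=1e-5)

    def test_ccs_limit_matches_dense_cis(self, water_sto3g_fc):
        system, ints, ref = water_sto3g_fc
        part = empty_partition(ref)
        cd = decompose(ints, part.C, tau=1e-10)
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-10)
        states = mlcc2.excited_states(gs, 3, tol=1e-9, seed=0)
        cis = ccs_excitation_vectors(ref, 3)
        for (w, _), (wc, _) in zip(states, cis):
            assert w == pytest.approx(wc, abs=1e-8)

    def test_davidson_seed_invariance(self, water_cc):
        ref, part, cd, ccsys, *_ = water_cc
        gs = mlcc2.ground_state(ref, part, cd, tol=1e-9)
        w1 = [w for w, _ in mlcc2.excited_states(gs, 2, tol=1e-8, seed=0)]
        w2 = [w for w, _ in mlcc2.excited_states(gs, 2, tol=1e-8, seed=99)]
        assert np.max(np.abs(np.array(w1) - np.array(w2))) < 1e-7
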