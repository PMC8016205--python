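# Methods

This note records the models implemented in `mlccx`, the conventions and
numerical choices that a maintainer needs to know, what the synthetic
fixtures do and do not emulate, and known limitations.

## Models

All methods are closed-shell and spin-adapted; open-shell input is
rejected at the `MolecularSystem` level.  The reference is restricted
Hartree–Fock, converged with DIIS on the AO orbital gradient
`FDS − SDF` (default threshold 1e-8 on its Frobenius norm, maximum 100
iterations).  The one-particle density convention is `D = C_occ C_occ^T`
(idempotent as `DSD = D`); all double-occupation factors of 2 live in the
Fock and energy expressions.

### Dressed formulation

Both MLCC2 and MLCCSD are formulated in the X1-transformed (dressed)
basis.  With `x1` the singles amplitudes placed in the virtual–occupied
block of a nilpotent matrix `t1`, the similarity transform of any
one-electron operator is `h~ = (I − t1) h (I + t1)`; Cholesky factors
dress the same way, `L~^J = (I − t1) L^J (I + t1)`, at cost
`O(n_MO^2 N_J)` per iteration.  Dressed two-electron integrals
`g~_pqrs = Σ_J L~^J_pq L~^J_rs` retain the pair-exchange symmetry but not
`(pq) ↔ (qp)`; the first index of each charge distribution is the
creation (bra) side.  The dressed residual equations were obtained by
spin-summing the standard spin-orbital CCSD equations
(Stanton–Gauss–Watts–Bartlett intermediates) at `t1 = 0` with dressed
integrals; every term is verified in the test suite against an
independent spin-orbital implementation at random amplitudes (agreement
to ~1e-15 per element).

A deliberate convention: the residual rows are normalized to equal the
mixed-spin spin-orbital residual components at the mapped amplitudes,
and amplitudes are parametrized over unique singlet pairs `ai ≥ bj`.
Because the singlet subspace is invariant under the Jacobian, its
eigenvalues in these coordinates are exactly the singlet excitation
energies — no biorthonormal bookkeeping is needed.

### Effective one-electron matrix

The CC layer receives `h = F0 − JK(L)`, where `F0` is the exact AO Fock
matrix transformed to the partition basis and `JK(L)` the mean field of
the *factorized* integrals.  At `x1 = 0` the dressed Fock then equals
`F0` to machine precision, so Brillouin's condition, the CCS limit
(`E_corr = 0` exactly), and the embedding identity hold independently of
the decomposition threshold; the `O(tau)` factorization error enters only
through the two-electron response terms, as intended.

### Jacobian actions

`jacobian_apply` evaluates the directional derivative of the same
residual function used for the ground state by a complex step,
`A r = Im[Omega(t + i h r)]/h` with `h = 1e-100`.  For the polynomial
residual this is exact to machine precision (no subtractive
cancellation), guarantees `A = dOmega/dt` by construction, and stays
matrix-free.  The acceptance suite independently checks the action
against real central finite differences (step 1e-5) to 1e-6.

### Solvers

Ground states use a quasi-Newton step preconditioned by orbital-energy
differences with DIIS acceleration (subspace 8, coefficients constrained
to sum to one, drop-oldest fallback on singular normal equations).  For
MLCC2 the doubles are eliminated analytically every iteration —
`s2 = −g~_aibj / (eps_a + eps_b − eps_i − eps_j)` over active indices —
which requires the semicanonical basis (active–active and
inactive–inactive occupied/virtual Fock blocks diagonal); the
`semicanonicalize` step enforces this and is checked by the solver.
Defaults: `|Omega| ≤ 1e-6` (ground), per-root residual `≤ 1e-4`
(excited).

Excited states use a non-symmetric Davidson iteration: orthonormal
subspace, dense eigensolve of the projected matrix, preconditioning by
orbital-energy denominators, subspace cap `20 n_roots` with collapse to
`2 n_roots`.  Start vectors are unit vectors on the smallest diagonal
estimates plus a tiny seeded perturbation (1e-8) that only breaks exact
ties; converged eigenvalues are seed-independent to well below 1e-7 on
all fixtures.  Transient complex Ritz pairs in a partial subspace are
iterated on their real parts; a persistent complex pair (25 consecutive
iterations, or an exact subspace) raises an error naming the offending
roots, since the target spectra here are real.

## Orbital spaces

*CNTOs.*  CCS (CIS) excitation vectors are computed in the retained
canonical basis (dense diagonalization up to dimension 4000, Davidson
beyond).  Approximate doubles follow the CIS(D)-style construction: the
one-index transforms of `(ai|bj)` along the excitation vector divided by
`eps_ab^ij − omega^CCS`, with a level shift (1e-6, warned) guarding
near-singular denominators.  The occupied/virtual matrices are Gram-type,
`M = R1 R1^T + (1/2) R2 R2^T`-contractions (mirrored for `N`), hence
symmetric positive semidefinite by construction; multiple states sum
their matrices element-wise.  Active orbitals are the top eigenvectors;
`n_v^a` defaults to the round-half-up virtual/occupied ratio rule.
Eigenvalue ties exactly at the cut are resolved by including the tied
orbitals (warned) to keep the selection basis-independent.

*Cholesky/PAO.*  Occupied localization is a pivoted Cholesky
decomposition of the AO density with pivots restricted to active-atom
AOs (default pivot threshold 1e-2); inactive occupieds are the
S-orthonormalized complement within the occupied span.  Active virtuals
are Löwdin-canonically orthonormalized PAOs `(I − DS)` restricted to
active-atom columns (linear-dependence cutoff 1e-6); inactive virtuals
additionally have the active virtuals projected out.  Radius-based region
selection keeps solvent molecules atomically (whole molecule in or out)
to avoid dangling bonds.

*Frozen-Fock embedding.*  Frozen orbitals (chemical cores, or environment
occupieds in reduced-space runs) contribute `F^f = 2J(D_f) − K(D_f)`
folded into the effective core Hamiltonian; virtuals outside the retained
span are simply dropped.  With nothing frozen the machinery reproduces
the standard calculation to 1e-9 on every reported quantity (tested).

## Cholesky ERI factorization

Step one selects pivots greedily on the (screened) residual diagonal,
with a Schwarz-style prescreen dropping pairs whose initial diagonal is
below `tau × 1e-2` (they can never exceed `tau` later, so the guarantee
is unaffected).  Ties on equal diagonals go to the lowest pair index for
cross-platform determinism.  Step two forms `S_KL = (K|L)` on the pivots,
its lower Cholesky factor `Q`, and assembles `L^J_pq = Σ_K (pq|K)
(Q^{-T})_{KJ}` directly in the MO basis, optionally batched over the
first MO index (results independent of batch size to 1e-12).

Unscreened termination (`max D ≤ tau`) bounds every AO-basis
reconstruction error by `tau`.  The MO-screened mode pivots on
`D~_ab = D_ab w_a w_b`, `w_a = (Σ_p |C_ap|)^2`.  Because the
Cauchy–Schwarz chain behind that surrogate carries a loose constant, the
implementation verifies the *exact* MO-projected residual diagonal at
termination (affordable at desk scale) and keeps pivoting with a
tightened effective threshold until it is `≤ tau`; the MO-basis error
bound is therefore rigorous, while the AO-basis residual may stay large —
screened-out AO integrals simply do not contribute to the retained MO
space.  In the degenerate full-space case this audit can cost a few more
vectors than the unscreened run; in reduced spaces (its intended use) it
yields substantially fewer.  Defaults: `tau = 1e-3` unscreened, `1e-4`
screened.

## AO integrals and basis sets

The McMurchie–Davidson engine evaluates overlap, kinetic, nuclear
attraction and the full in-core ERI tensor over contracted cartesian
Gaussians (s, p, 6-component d), with numba-compiled kernels, Boys
function by a non-alternating Kummer series with downward recursion
(upward asymptotic branch above x = 35), and exact 8-fold ERI symmetry by
computing canonical shell quartets once.  Each contracted AO is
renormalized to unit self-overlap, which changes no observable.  STO-3G
and cc-pVDZ parameters for H, C, N, O are embedded as plain-text tables;
per-atom basis assignment supports the mixed higher-level/environment
basis layout used in reduced-space runs.  Everything is held in core:
the ERI tensor is `O(N_AO^4)` memory, which caps practical problem sizes
at roughly 100 AOs — deliberate desk scale.

## Synthetic fixtures

`generate_solvated_fixture` packs rigid water molecules, uniformly
oriented, into a shell around a solute with a 1.5 Å clash floor,
deterministically for a fixed seed.  It emulates the geometry *layout* of
a chromophore in an explicit solvent shell — localized excitation, nested
spatial regions, many spectator orbitals — which is what the multilevel
and reduced-space machinery exercises.  It does not emulate hydrogen-bond
network statistics, thermal sampling, or bulk solvation energetics, so
passing tests demonstrate correctness of the orbital-space machinery and
convergence behavior, not solvatochromic accuracy.  Test problem sizes
(water/cc-pVDZ, 25 AOs; formaldehyde + 10 waters/STO-3G, 82 AOs) were
chosen as the smallest systems that still have a localized chromophore
inside a genuine environment.

## Verification strategy

The package is anchored to independent oracles rather than literature
tables: a spin-orbital CCSD/CC2 implementation (explicit t1, dense
antisymmetrized integrals, finite-difference Jacobian) lives in the test
suite and must agree with the dressed closed-shell code on residuals at
random amplitudes, converged energies, and excitation energies; CCS
limits are checked against dense CIS diagonalization; the integral
engine is checked against closed-form s-shell ERIs, the incomplete-gamma
Boys function, rotational invariance, and a full-diagonalization SCF; and
the two-electron oracle chain is pinned by CCSD = FCI for H2.

## Known limitations

Energies only (no transition moments, properties or gradients); two-level
CCS/CCSD only (no CCS/CC2/CCSD three-level operator, no triples); real
orbitals, no point-group symmetry, no periodicity; the multilevel HF
reference optimization is out of scope (the reduced space uses a standard
RHF reference with frozen-Fock embedding); in-core tensors throughout.
Left eigenvectors are not computed, so excitation energies come without
oscillator strengths.
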