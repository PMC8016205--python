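# mlccx

Multilevel coupled cluster (MLCC2 and CCS/CCSD MLCCSD) excitation energies
in reduced orbital spaces, with two-step MO-screened Cholesky factorization
of the electron-repulsion integrals — as a desk-scale, fully tested Python
library and CLI.

## The problem

Coupled cluster excitation energies are accurate but expensive: CC2 scales
as O(N^5) and CCSD as O(N^6) with system size.  For a localized property —
say the lowest excitation of a chromophore in a solvent shell — most of
that effort is wasted on orbitals that barely participate.  Multilevel
coupled cluster restricts the *double* excitation operator to an active
orbital space while keeping the single excitations (and hence orbital
relaxation) unrestricted:

* **MLCC2** — cluster operator `X1 + S2`, with `S2` treated perturbatively
  and restricted to active occupied/virtual orbitals.  Ground state:
  `<mu1| exp(-X1) (H + [H, S2]) exp(X1) |HF> = 0` with the `S2` equation
  solved analytically each iteration in a semicanonical basis.
* **MLCCSD** (CCS/CCSD) — `X1 + T2` with the standard CCSD equations,
  except `T2` and the doubles projection space are active-restricted.

Excitation energies `omega` are right eigenvalues of the Jacobian
`A = dOmega/dt`, obtained matrix-free with a non-symmetric Davidson solver.
With every orbital active the models *are* CC2/CCSD; with none they reduce
to CCS — these limits are enforced numerically in the test suite against an
independent spin-orbital implementation.

Active orbitals are selected either by **correlated natural transition
orbitals** (CNTOs: eigenvectors of occupied/virtual density-like matrices
M and N built from CCS excitation vectors plus CIS(D)-style approximate
doubles) or spatially, by **Cholesky occupied orbitals** (restricted
pivoted Cholesky of the HF density) and **projected atomic orbitals**
(PAOs) for the virtual space.  For large environments a **frozen-Fock
reduced space** is used: environment occupieds contribute only a static
mean-field term `F^f` to the Fock matrix, and the correlated calculation
runs in n_MO << N_AO orbitals.

Integrals are handled by a **two-step pivoted Cholesky decomposition** of
the ERI matrix: the pivot set ("Cholesky basis") is selected first by
greedy max-diagonal pivoting; the factors are then built *directly in the
MO basis* through an RI-like expression, so AO-basis vectors are never
stored.  An MO-screened variant pivots on a screened diagonal
`D~_ab = D_ab w_a w_b`, `w_a = (sum_p |C_ap|)^2`, yielding fewer vectors
while guaranteeing that the MO-basis reconstruction error stays below the
threshold `tau` (the package audits the exact MO-projected residual
diagonal to make that guarantee rigorous).

AO integrals come from an in-repo McMurchie–Davidson engine (numba-jitted;
cartesian Gaussians; STO-3G and cc-pVDZ for H/C/N/O embedded) behind a
pluggable integral-provider contract.

## Worked example

Lowest two singlet excitations of water, CC2/STO-3G versus a small
CNTO-based MLCC2 active space:

```bash
mlccx run water.xyz --method cc2   --basis sto-3g --n-states 2 --out cc2.json
mlccx run water.xyz --method mlcc2 --basis sto-3g --active-occ 2 --active-virt 1 \
      --n-states 2 --out mlcc2.json
mlccx compare mlcc2.json cc2.json
```

The first run prints

```
# eV conversion: 27.211386 eV/hartree
n_AO 7  n_MO 6  N_J 22  active (o,v) = (4, 2)
SCF energy         -74.9630231224 hartree
total energy       -74.9985609347 hartree
correlation        -0.0355378124 hartree
omega_1   0.47358775 hartree   12.886979 eV
omega_2   0.55607924 hartree   15.131687 eV
```

i.e. the frozen-core CC2 correlation energy (−35.5 mE_h) and the two
lowest excitation energies.  `mlccx compare` then tabulates the
active-space convergence (deltas relative to the largest space):

```
  method  n_o^a  n_v^a  omega [eV]  delta [eV]
   mlcc2      2      1   13.2725  15.0987   +0.3856  -0.0330
     cc2      4      2   12.8870  15.1317   +0.0000  +0.0000
```

With two of four occupied and one of two virtual orbitals active, MLCC2
reproduces the second CC2 excitation to 0.03 eV at a fraction of the
doubles work; growing the space drives both states to the CC2 limit.
Reduced-space runs add `--r-cc`/`--r-ccsd` radii (Angstrom) and the
`cholesky-pao` scheme; `--cd-screen` switches on the MO-screened
decomposition.  Every key in the YAML config is mirrored by a CLI flag.

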