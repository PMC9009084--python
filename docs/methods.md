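# Methods

This note records the model, the numerical choices, and what the
synthetic test systems do and do not probe.  It is the package's own
account; every number quoted here is produced by the test suite or by
`scripts/acceptance.py`.

## Model and assumptions

**Interaction energy.**  For a two-fragment adduct the method computes
`ΔE_int^HFLD = ΔE_int^ref + E_disp^C-CCSD`.  The decomposition is
additive by construction; the package stores all three numbers and the
identity is exact.

**Reference part.**  `ΔE_int^ref` is a supermolecular,
counterpoise-corrected difference of single-determinant energies, all
evaluated at the adduct geometry with the monomers keeping the partner
fragment's basis functions as ghost centers.  Fragment charges and
multiplicities for the monomer calculations are user input — they
cannot be inferred from the adduct, and high-spin/low-spin coupling
choices are the user's.  Three reference schemes exist:

* UHF/HFLD — UHF energies in the reference part (package default);
* QRO/HFLD — energies of the quasi-restricted-orbital determinant;
* ROHF/HFLD — ROHF throughout.

For a closed-shell system all three coincide exactly; the test suite
checks agreement to 1e-6 kcal/mol on the water dimer (measured spread:
~4e-10 kcal/mol).

**Dispersion part.**  The correlation treatment always runs on a
*spin-restricted* determinant: QRO for the UHF and QRO schemes, ROHF
for ROHF/HFLD.  Occupied orbitals (frozen core excluded) are
Foster–Boys localized per spin and assigned to fragments by Mulliken
population; the occupied spin pairs (αα, ββ, αβ) are classified
intra-/interfragment.  Semicanonical MP2 pair energies (diagonal
occupied Fock elements, canonical virtual energies) screen the pairs:
`|ε_pair| ≥ T_CutPairs` → strong (boundary inclusive).  The
unrestricted CCSD equations are then solved with doubles active only
for the strong *interfragment* pairs; intrafragment pairs are dropped
entirely (their MP2 energies are retained as diagnostics) and weak
interfragment pairs stay at second order.  The LED step rotates the
converged amplitudes into the Foster–Boys-localized virtual basis
(each total pair energy is invariant under this rotation) and keeps,
as dispersion, the part of each pair sum whose two virtuals sit on
opposite fragments — genuine and exchange patterns both.  Finally
`E_disp^C-CCSD = Σ ε_disp(strong inter) + E_WP(inter)`.

**Singles policy.**  All singles amplitudes stay active regardless of
the pair restriction (they are cheap, and for non-Brillouin restricted
references the occupied–virtual Fock blocks couple into both residuals
and the energy).  A flag (`keep_all_singles=False`) restricts singles
to occupied orbitals that appear in an active pair, for users who want
the tighter restriction; the default keeps them all.

**Virtual space.**  Canonical virtuals are used in the CC solve — the
untruncated limit of a pair-natural-orbital treatment; no PNO
construction or truncation is performed.  Consequently the CPS
(complete-PNO-space) extrapolation utility is a standalone
calculator (`E = E_X + F·(E_Y − E_X)`, default F = 1.5, both exposed)
and is never applied to HFLD energies inside the pipeline: with the
pair restriction the dependence of the correlation energy on the PNO
space is not smooth enough for that extrapolation to be reliable.

## Mean-field layer

AO integrals are exact four-index McMurchie–Davidson over contracted
cartesian Gaussians (numba-jitted kernels; Boys function by series /
downward recursion below x = 35 and upward recursion above).  No RI or
chain-of-spheres approximation is used, removing one error source at
the cost of desk-scale system sizes.  Basis parameters (STO-3G,
cc-pVDZ, aug-cc-pVDZ, H–Ne) are transcribed from the standard
published sets into a plain-text library; a basis spec may override
single elements (`"cc-pvdz;F=aug-cc-pvdz"`).  Cartesian d components
are individually normalized.

SCF: UHF and ROHF with Pulay DIIS; ROHF uses the Roothaan effective
Fock with Guest–Saunders diagonal coupling (this pins the Fock matrix
entering the correlation denominators).  Convergence defaults: 1e-9
hartree in energy with a 1e-6 orbital-gradient cap.  Two safeguards
matter in practice:

* **Level-shift retry.**  Open-shell systems with near-degenerate
  holes (a halogen p hole) can make plain DIIS oscillate; on failure
  the solver retries with a 0.3 then 1.0 hartree virtual level shift
  and heavier early damping.
* **Fragment-superposition guess.**  For adducts, the core-Hamiltonian
  guess can converge to spurious charge-transfer SCF states (observed
  ~0.2 hartree too high for the fluorine–water hemibond, with a
  spurious F–O bond order).  The pipeline therefore seeds every adduct
  SCF with the summed spin densities of the two ghosted-monomer
  solutions, whose traces are consistent with the adduct by
  construction.

**QRO construction.**  From a converged UHF solution, the SVD of the
α–β occupied overlap yields corresponding orbital pairs with overlaps
σᵢ; the normalized symmetric combinations (the UHF natural orbitals
with occupation 1+σᵢ) form the doubly occupied space, the unpaired α
corresponding orbitals the SOMOs, and the S-orthogonal complement the
virtuals.  Each block is semicanonicalized with the spin-averaged Fock
of the resulting determinant.  The determinant energy obeys
E_UHF ≤ E_ROHF ≤ E_QRO; for triplet CH₂/cc-pVDZ the QRO determinant
sits 0.2 mhartree above the independently converged ROHF minimum.

**⟨S²⟩** is evaluated exactly for the single determinant
(S_z(S_z+1) + n_β − Σ|⟨φᵢᵅ|φⱼᵝ⟩|²) and recorded for every
calculation; restricted determinants give S(S+1) to machine precision.
The ²CO⁺ radical cation shows a deviation of 0.224 from the doublet
value at cc-pVDZ — past the 0.2 warning threshold at which the UHF
reference becomes questionable.

**Mayer bond order** uses spin-resolved densities,
`B_AB = 2 Σ [(PᵅS)(PᵅS) + (PᵝS)(PᵝS)]` over AO blocks of the two
atoms, reducing to the textbook closed-shell formula when Pᵅ = Pᵝ.

## Coupled-cluster layer

Spin-orbital CCSD with the standard factorized intermediates, full
(non-diagonal) Fock: off-diagonal occupied couplings from
localization and occupied–virtual blocks from non-Brillouin restricted
references enter the residuals; diagonal elements supply the update
denominators.  DIIS (subspace 8) on the amplitude step; semicanonical
MP2 initial guess; convergence |dE| < 1e-8 hartree and amplitude-step
RMS < 10× that (tests tighten to 1e-12 where oracle agreement at
1e-10 is asserted).  The pair restriction is a projection applied
every iteration: doubles rows of inactive pairs are pinned at zero and
their residuals ignored.  Denominators below 1e-8 hartree raise an
error rather than producing silent garbage.

Pair energies `ε_ij = ½ Σ_ab ⟨ij||ab⟩ τ_ij^ab` (i < j over occupied
spin orbitals) plus the singles energy Σ F_ia t_ia reproduce the total
correlation energy exactly — a bookkeeping identity the suite asserts
at 1e-12.

**Oracles.**  Two independent code paths check the solver: exact
diagonalization in the determinant basis (FCI, Slater–Condon rules),
and a CCSD oracle that builds e^T|0⟩ explicitly in the determinant
space and iterates the projected equations ⟨μ|(H−E)e^T|0⟩ = 0 — no
residual algebra is shared with the main solver.  Full-pair mode
matches the oracle to ≤1e-9 hartree on H₂/STO-3G, He₂/cc-pVDZ and
triplet CH₂/STO-3G, and matches FCI to ≤1e-10 on two-electron
systems.

## Synthetic systems: what they show and what they do not

All fixtures are rigid-monomer geometries from standard experimental
internals (water r_OH = 0.9572 Å, ∠HOH = 104.52°; triplet CH₂
r_CH = 1.077 Å, ∠HCH = 134°; CO⁺ r = 1.115 Å; methane r_CH = 1.087 Å)
placed along documented approach axes, regenerated bit-identically
from their parameters.  They emulate the radical–solvent and carbene
adduct families at desk scale; they are *not* the benchmark-set
geometries (those are correlated-level optimized structures), so
paper-grade numbers are reproduced in class and sign, not digit by
digit.  User-supplied XYZ geometries go through the normal reader for
exact-structure work.

Desk-scale problem sizes: Li/F–water adducts at cc-pVDZ (~40 cartesian
AOs, with full-pair CCSD affordable for the ΔE_no-disp companion),
He₂ tail at aug-cc-pVDZ, reference-scheme consistency at STO-3G (the
closed-shell coincidence being basis-independent), and a CH₄·(H₂O)₃
cluster at STO-3G for the dispersion-density map.

Behaviour the suite demonstrates at these sizes:

* He₂ dispersion tail: log–log slope −6.00 over 8–15 Å (London R⁻⁶);
  the implied C₆ ≈ 1.5 a.u. is close to the accepted He₂ value.
* ²Li···OH₂: mean-field-bound with dispersion on top
  (ΔE_ref = −11.6, E_disp = −1.09, ΔE_no-disp = +0.42 kcal/mol at
  cc-pVDZ) — the dispersion-dominated-correlation case; the HFLD curve
  tracks full CCSD far more closely than bare HF at every scanned
  separation.
* ²F···OH₂ hemibond: repulsive at HF, QRO-level Mayer F–O order 0.00 —
  the mean-field picture with no charge sharing.  The large *negative*
  nondispersive correlation known for this system at quintuple-zeta
  does **not** appear at the shipped double-zeta scale (measured
  +0.37 kcal/mol; unchanged in sign with diffuse augmentation of F):
  the charge-transfer correlation that drives it is strongly
  basis-hungry.  The corresponding acceptance assertion is kept at its
  stated form and fails at desk scale; passing tests here demonstrate
  the mean-field diagnostics and the machinery, not the converged-basis
  energetics of hemibonds.
* Noninteracting limits at 50 Å: |E_disp| < 1e-8 hartree,
  |ΔE_int^HFLD| < 1e-6 kcal/mol, Mayer order ~0, Δρ^ref ~0.

## Other numerical choices

* **Localization:** Jacobi-sweep Foster–Boys with fixed ascending pair
  order (deterministic); convergence when the best 2×2 gain in a sweep
  drops below `loc_conv` (1e-6); an objective decrease raises an
  error.  The augmented-Hessian variant used by large production codes
  seeks the same stationary points; plain Jacobi is simpler and
  reproducible.  Virtual-space localization of diffuse bases can be
  slow to tighten — the 400-sweep cap logs a warning rather than
  failing.
* **Fragment assignment:** Mulliken by default, Löwdin behind a config
  switch (more robust with diffuse functions); exact 50/50 ties go to
  fragment X with a logged warning.
* **Frozen core:** none for H–He, the 1s for Li–Ne, the Ne shell for
  Na–Ar; user-overridable by disabling `frozen_core`.
* **CBS extrapolation:** reference part
  `E(X) = E_CBS + A exp(−α√X)` with α = 4.42 (D/T) or 5.79 (T/Q)
  defaults, correlation part `(Y³E_Y − X³E_X)/(Y³ − X³)` (β = 3); all
  constants config-exposed since different programs pin slightly
  different α values.
* **DID kernel:** ρ_DID(r) = Σ_pairs ε_disp^ij · ½(|φᵢ|² + |φⱼ|²)
  over localized occupied orbitals — a symmetric occupied-density
  weighting whose grid integral equals the mapped energy by
  construction (asserted at 1% quadrature accuracy).  Weak
  interfragment pairs are mapped with their MP2 energies by default.
* **Units:** Å in files, bohr and hartree internally, kcal/mol in
  reports (1 hartree = 627.5094740631 kcal/mol).

## Known limitations

* No perturbative triples: HFLD's accuracy rests partly on error
  cancellation that (T) would otherwise absorb; systems with large
  nondispersive correlation are out of reach of any
  dispersion-corrected mean-field method.
* Desk-scale only: exact four-index integrals and dense spin-orbital
  CC tensors cap practical sizes near ~60 atoms' worth of basis
  functions on one core.
* Basis library covers H–Ne at the double-zeta level; heavier elements
  and triple-zeta sets require user-supplied parameters.
* The correlation part of density-deformation maps (and CC-level Mayer
  orders) would need a CC one-particle density, which is not
  implemented; Δρ maps are reference-level only.
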