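# hfld — open-shell HFLD interaction energies

`hfld` computes **London-dispersion-corrected Hartree–Fock interaction
energies for open-shell (and closed-shell) molecular adducts**.  It is
aimed at the study of noncovalent interactions — radical–solvent
complexes, carbene adducts, ionic bonds — where plain Hartree–Fock
misses dispersion entirely and empirically dispersion-corrected
mean-field methods carry fitted parameters.

## The method

For a two-fragment adduct *XY* the HFLD interaction energy is the sum
of a mean-field part and a coupled-cluster-level London dispersion
part:

```
ΔE_int^HFLD = ΔE_int^ref + E_disp^C-CCSD            (additive by construction)
```

* **ΔE_int^ref** is the counterpoise-corrected (Boys–Bernardi, ghost
  atoms) interaction energy of a mean-field reference.  Three schemes
  are supported: UHF/HFLD (default), QRO/HFLD and ROHF/HFLD, which
  differ only in the determinant used for the reference part.
* **E_disp^C-CCSD** comes from solving the unrestricted CCSD amplitude
  equations on a spin-restricted determinant (the quasi-restricted
  orbital determinant built from UHF, or ROHF) **with doubles
  restricted to interfragment occupied pairs**: occupied orbitals are
  Foster–Boys localized and assigned to fragments by Mulliken
  population; pairs with both orbitals on one fragment are dropped.
  Interfragment pairs are screened on their semicanonical MP2 pair
  energies (threshold `T_CutPairs`, default 1e-5 hartree): strong pairs
  enter the CC solve, weak pairs are kept at second order.  A local
  energy decomposition (LED) then splits each strong-pair energy into
  its dispersion part — double excitations whose two virtual orbitals
  sit on *opposite* fragments, in both the genuine (i_X→a_X, j_Y→b_Y)
  and exchange (i_X→a_Y, j_Y→b_X) patterns — and a nondispersive rest.
  The interfragment weak-pair energy, essentially dispersive, is added
  in full:

```
E_disp^C-CCSD = Σ_strong-inter ε_disp(ij) + E_WP(inter)
```

The scheme has **no empirical parameters**.  Virtual orbitals are kept
canonical during the CC solve (the untruncated pair-natural-orbital
limit) and Foster–Boys localized for the fragment assignment of the
dispersion excitations.

Diagnostics around the main method: UHF spin contamination ⟨S²⟩,
Mayer bond orders from spin-resolved densities, the reference part of
the one-electron density deformation Δρ^ref on cube grids, the
nondispersive correlation contribution ΔE_no-disp^C-CCSD (from a
companion full-pair CCSD), the dispersion interaction density (DID)
real-space map of E_disp, and two-point CBS / CPS extrapolation
utilities.

## Worked example

The helium dimer at 3.0 Å — bound *only* by dispersion:

```bash
$ hfld fixtures build he2 --sep 3.0 -o he2.xyz
$ hfld run he2.xyz --fragments "1:X,2:Y" --basis cc-pvdz
reference scheme      : UHF/HFLD
basis                 : cc-pvdz
T_CutPairs            : 1.0e-05 hartree
<S^2> (adduct)        : 0.0000
dE_int^ref            :       0.0138 kcal/mol
E_disp^C-CCSD         :      -0.0039 kcal/mol
dE_int^HFLD           :       0.0100 kcal/mol
```

Hartree–Fock alone is repulsive (+0.014 kcal/mol); the CC-level
dispersion term is attractive and pulls the interaction energy down.
(cc-pVDZ carries little polarization for He; with `--basis
aug-cc-pvdz` the dispersion term grows and a shallow van der Waals
minimum appears near 3 Å.)

The same pipeline from Python, for an open-shell adduct:

```python
from hfld import build_dimer, fixture_config, hfld_interaction_energy

geometry = build_dimer("li_h2o")            # ²Li···OH2, d(Li-O) = 1.90 Å
config = fixture_config("li_h2o")           # doublet Li / singlet water
result = hfld_interaction_energy(geometry, config)
print(result.de_ref_kcal, result.e_disp_kcal, result.de_hfld_kcal)
# -11.631  -1.090  -12.720   (kcal/mol, UHF/HFLD, cc-pVDZ)
```

The metal–water bond is already captured at the mean-field level
(−11.6 kcal/mol) and dispersion adds about −1.1 kcal/mol — the
dispersion-dominated-correlation situation where dispersion-corrected
HF methods work well.

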