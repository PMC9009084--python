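"""Reference determinants and mean-field diagnostics.

HFLD extracts its dispersion energy from a coupled-cluster solve on a
spin-restricted determinant: either the ROHF determinant or the
quasi-restricted-orbital (QRO) determinant built from a converged UHF
solution via the corresponding-orbital transformation.  This module
builds those references and the diagnostics used around them:
spin contamination <S^2>, Mayer bond orders, Boys-Bernardi counterpoise
interaction energies and the reference part of the one-electron density
deformation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
import scipy.linalg as sla

from .geometry import (
    FragmentedGeometry, CubeGrid, make_ghost_system, HARTREE_TO_KCAL,
)
from .integrals import AOIntegralSet, ao_values
from .scf import SCFSolution, solve_scf, _jk, _uhf_energy


@dataclass
class ReferenceState:
    """A single-determinant reference with per-spin Fock matrices.

    For UHF the two spatial orbital sets differ; for ROHF and QRO a
    single spatial set is shared and the determinant is spin-restricted
    (n_alpha - n_beta singly occupied orbitals).  ``fock_ao`` holds the
    true spin Fock operators of THIS determinant's density, whose MO
    representation supplies the F_ia blocks entering the singles part of
    the correlation energy and the CC residuals.
    """

    kind: str
    geometry: FragmentedGeometry
    ao: AOIntegralSet
    C: tuple[np.ndarray, np.ndarray]
    fock_ao: tuple[np.ndarray, np.ndarray]
    energy: float
    n_occ: tuple[int, int]
    s_squared: float
    n_frozen_core: int

    @property
    def eps(self) -> tuple[np.ndarray, np.ndarray]:
        """Diagonal MO Fock elements per spin (semicanonical energies)."""
        return tuple(
            np.einsum("mi,mn,ni->i", C, F, C, optimize=True)
            for C, F in zip(self.C, self.fock_ao)
        )

    @property
    def density(self) -> tuple[np.ndarray, np.ndarray]:
        na, nb = self.n_occ
        Pa = self.C[0][:, :na] @ self.C[0][:, :na].T
        Pb = self.C[1][:, :nb] @ self.C[1][:, :nb].T
        return Pa, Pb

    @property
    def sz(self) -> float:
        return 0.5 * (self.n_occ[0] - self.n_occ[1])


def spin_squared(C: tuple, S: np.ndarray, n_occ: tuple) -> float:
    """<S^2> of a single determinant.

    S_z(S_z+1) + n_beta - sum_ij |<phi_i^a|phi_j^b>|^2 over occupied
    pairs; exact (equal to S(S+1)) for restricted determinants.
    """
    na, nb = n_occ
    sz = 0.5 * (na - nb)
    M = C[0][:, :na].T @ S @ C[1][:, :nb]
    return sz * (sz + 1.0) + nb - float((M * M).sum())


def reference_from_scf(sol: SCFSolution, frozen_core: bool = True) -> ReferenceState:
    geom = sol.ao.basis.geometry
    s2 = spin_squared(sol.C, sol.ao.overlap, sol.n_occ)
    return ReferenceState(
        kind=sol.kind,
        geometry=geom,
        ao=sol.ao,
        C=sol.C,
        fock_ao=sol.fock_ao,
        energy=sol.energy,
        n_occ=sol.n_occ,
        s_squared=s2,
        n_frozen_core=geom.n_core if frozen_core else 0,
    )


def build_qro(uhf: SCFSolution | ReferenceState, frozen_core: bool = True) -> ReferenceState:
    """Quasi-restricted orbitals from a converged UHF solution.

    Corresponding-orbital route: SVD of the alpha-beta occupied overlap
    rotates both occupied sets into maximally-pairing orbitals with
    overlaps sigma_i.  The normalized symmetric combinations of each
    pair - the UHF natural orbitals with occupation 1 + sigma_i -
    become the doubly occupied space, the unpaired alpha corresponding
    orbitals the SOMOs, and the virtual space is the S-orthogonal
    complement.  Each block is then semicanonicalized with the
    spin-averaged Fock of the resulting determinant.  The determinant
    energy satisfies E_QRO >= E_UHF (variational ordering).
    """
    if isinstance(uhf, SCFSolution):
        if uhf.kind != "UHF":
            raise ValueError("build_qro expects a UHF solution")
        ao, C, n_occ = uhf.ao, uhf.C, uhf.n_occ
    else:
        ao, C, n_occ = uhf.ao, uhf.C, uhf.n_occ
    na, nb = n_occ
    if na < nb:
        raise ValueError("alpha must be the majority spin")
    S = ao.overlap
    Ca_occ = C[0][:, :na]
    Cb_occ = C[1][:, :nb]
    M = Ca_occ.T @ S @ Cb_occ
    U, sv, Vt = np.linalg.svd(M)
    A = Ca_occ @ U                 # alpha corresponding orbitals
    B = Cb_occ @ Vt.T              # beta corresponding orbitals
    # doubly occupied QROs: symmetric pair combinations (UHF natural
    # orbitals with occupation 1 + sigma), normalized in the S metric
    domo = (A[:, :nb] + B) / np.sqrt(2.0 * (1.0 + sv))
    somo = A[:, nb:]               # unpaired alpha space
    occ = np.hstack([domo, somo])
    # virtual space: project occupied span out of the alpha virtuals
    P_occ = occ @ occ.T
    V0 = C[0][:, na:] - P_occ @ S @ C[0][:, na:]
    Mv = V0.T @ S @ V0
    ev, W = np.linalg.eigh(Mv)
    keep = ev > 1e-8
    virt = V0 @ (W[:, keep] / np.sqrt(ev[keep]))
    Cq = np.hstack([occ, virt])

    # determinant energy and Fock from the QRO density
    Pa = Cq[:, :na] @ Cq[:, :na].T
    Pb = Cq[:, :nb] @ Cq[:, :nb].T
    eri, h = ao.eri, ao.hcore
    Ja, Ka = _jk(eri, Pa)
    Jb, Kb = _jk(eri, Pb)
    Fa = h + Ja + Jb - Ka
    Fb = h + Ja + Jb - Kb
    energy = _uhf_energy(h, Fa, Fb, Pa, Pb, ao.e_nuclear)

    # semicanonicalize within (doubly, singly, virtual) blocks
    Favg = 0.5 * (Fa + Fb)
    blocks = [slice(0, nb), slice(nb, na), slice(na, Cq.shape[1])]
    Cq = Cq.copy()
    for blk in blocks:
        sub = Cq[:, blk]
        if sub.shape[1] == 0:
            continue
        f = sub.T @ Favg @ sub
        w, R = np.linalg.eigh(0.5 * (f + f.T))
        Cq[:, blk] = sub @ R

    geom = ao.basis.geometry
    return ReferenceState(
        kind="QRO",
        geometry=geom,
        ao=ao,
        C=(Cq, Cq),
        fock_ao=(Fa, Fb),
        energy=energy,
        n_occ=n_occ,
        s_squared=spin_squared((Cq, Cq), S, n_occ),
        n_frozen_core=geom.n_core if frozen_core else 0,
    )


def build_reference(
    geometry: FragmentedGeometry,
    basis_name: str,
    kind: str = "UHF",
    scf_conv: float = 1e-9,
    maxiter: int = 300,
    frozen_core: bool = True,
    ao: AOIntegralSet | None = None,
    guess_density: tuple[np.ndarray, np.ndarray] | None = None,
) -> ReferenceState:
    """SCF + reference construction in one step (kind: UHF, ROHF or QRO)."""
    kind = kind.upper()
    scf_kind = "ROHF" if kind == "ROHF" else "UHF"
    sol = solve_scf(geometry, basis_name, scf_kind, scf_conv, maxiter, ao=ao,
                    guess_density=guess_density)
    if kind == "QRO":
        return build_qro(sol, frozen_core)
    return reference_from_scf(sol, frozen_core)


def fragment_superposition_guess(
    geometry: FragmentedGeometry,
    basis_name: str,
    fragment_charges: dict,
    fragment_multiplicities: dict,
    scf_conv: float = 1e-7,
    maxiter: int = 300,
    ao: AOIntegralSet | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Summed spin densities of the two ghosted monomers.

    Solved in the full adduct basis, so the result seeds the adduct SCF
    with the correct electron assignment per fragment; the spin traces
    match the adduct's (n_alpha, n_beta) because the fragment charges
    and multiplicities must be consistent with the adduct's.
    """
    from .integrals import build_ao_integrals

    Pa = Pb = None
    for frag in ("X", "Y"):
        mono = make_ghost_system(
            geometry, frag, fragment_charges[frag], fragment_multiplicities[frag]
        )
        mono_ao = build_ao_integrals(mono, basis_name, reuse=ao)
        sol = solve_scf(mono, basis_name, "UHF", scf_conv, maxiter, ao=mono_ao)
        pa, pb = sol.density
        Pa = pa if Pa is None else Pa + pa
        Pb = pb if Pb is None else Pb + pb
    return Pa, Pb


# -- counterpoise -----------------------------------------------------------

@dataclass
class CounterpoiseResult:
    """Boys-Bernardi counterpoise-corrected interaction energy (hartree)."""

    e_adduct: float
    e_x: float
    e_y: float

    @property
    def delta_e(self) -> float:
        return self.e_adduct - self.e_x - self.e_y

    @property
    def delta_e_kcal(self) -> float:
        return self.delta_e * HARTREE_TO_KCAL


def counterpoise_interaction(
    geometry: FragmentedGeometry,
    energy_fn: Callable[[FragmentedGeometry], float],
    fragment_charges: dict,
    fragment_multiplicities: dict,
) -> CounterpoiseResult:
    """Counterpoise-corrected interaction energy.

    Every term is evaluated at the adduct geometry in the full adduct
    basis: the monomer calculations keep the partner fragment's basis
    functions as ghosts.  ``energy_fn`` maps a geometry to an energy and
    is the method being corrected (HF, QRO, CCSD, ...).
    """
    if geometry.is_monomer:
        raise ValueError("counterpoise needs a two-fragment adduct")
    energies = {}
    try:
        energies["adduct"] = energy_fn(geometry)
    except Exception as exc:
        raise RuntimeError(f"adduct calculation failed: {exc}") from exc
    for frag in ("X", "Y"):
        mono = make_ghost_system(
            geometry, frag, fragment_charges[frag], fragment_multiplicities[frag]
        )
        try:
            energies[frag] = energy_fn(mono)
        except Exception as exc:
            raise RuntimeError(
                f"ghosted monomer {frag} calculation failed: {exc}"
            ) from exc
    return CounterpoiseResult(
        e_adduct=energies["adduct"], e_x=energies["X"], e_y=energies["Y"]
    )


# -- Mayer bond order -------------------------------------------------------

def mayer_bond_order(
    density: tuple[np.ndarray, np.ndarray],
    overlap: np.ndarray,
    ao_atom: np.ndarray,
    atom_a: int,
    atom_b: int,
) -> float:
    """Open-shell Mayer bond order between two atoms (electrons).

    B_AB = 2 sum_{mu in A, nu in B} [(P^a S)_mn (P^a S)_nm
                                     + (P^b S)_mn (P^b S)_nm];
    reduces to the textbook closed-shell formula when P^a = P^b.
    """
    if atom_a == atom_b:
        raise ValueError("Mayer bond order needs two distinct atoms")
    Pa, Pb = density
    PSa = Pa @ overlap
    PSb = Pb @ overlap
    ma = ao_atom == atom_a
    mb = ao_atom == atom_b
    return 2.0 * float(
        (PSa[np.ix_(ma, mb)] * PSa[np.ix_(mb, ma)].T).sum()
        + (PSb[np.ix_(ma, mb)] * PSb[np.ix_(mb, ma)].T).sum()
    )


# -- reference density deformation ------------------------------------------

def density_on_grid(ref: ReferenceState, points: np.ndarray) -> np.ndarray:
    """Total electron density of the determinant on arbitrary points."""
    phi = ao_values(ref.ao.basis, points)     # (nao, npts)
    Pa, Pb = ref.density
    P = Pa + Pb
    return np.einsum("mp,mn,np->p", phi, P, phi, optimize=True)


def reference_density_deformation(
    adduct: ReferenceState,
    monomer_x: ReferenceState,
    monomer_y: ReferenceState,
    grid: CubeGrid,
) -> np.ndarray:
    """Reference part of the density deformation on a grid.

    Delta rho^ref(r) = rho_adduct - rho_X - rho_Y with the monomers
    evaluated in the full (ghosted) adduct basis, so all three densities
    live on one AO set; integrates to zero when the fragment electron
    counts add up to the adduct's.
    """
    n_ad = adduct.geometry.n_electrons
    n_x = monomer_x.geometry.n_electrons
    n_y = monomer_y.geometry.n_electrons
    if n_ad != n_x + n_y:
        raise ValueError(
            f"electron counts inconsistent: adduct {n_ad} != {n_x} + {n_y}"
        )
    pts = grid.points()
    rho = (
        density_on_grid(adduct, pts)
        - density_on_grid(monomer_x, pts)
        - density_on_grid(monomer_y, pts)
    )
    return rho.reshape(grid.shape)
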