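"""Self-consistent field solutions: UHF and ROHF with DIIS.

The solver is deliberately plain: exact four-index integrals, core
(or supplied) guess, Pulay DIIS on the orthonormal-basis gradient
FPS - SPF, with damping on the first few cycles.  ROHF uses the
Roothaan single-Hamiltonian construction (Guest-Saunders diagonal
coupling), which pins the Fock matrix entering the correlation
denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .geometry import FragmentedGeometry
from .integrals import AOIntegralSet, build_ao_integrals


class SCFError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class SCFSolution:
    """Converged mean-field determinant (spin-unrestricted storage)."""

    kind: str                  # "UHF" or "ROHF"
    energy: float
    C: tuple[np.ndarray, np.ndarray]        # MO coefficients per spin
    eps: tuple[np.ndarray, np.ndarray]      # orbital energies per spin
    fock_ao: tuple[np.ndarray, np.ndarray]  # true spin Fock matrices, AO basis
    n_occ: tuple[int, int]
    converged: bool
    n_iter: int
    ao: AOIntegralSet

    @property
    def density(self) -> tuple[np.ndarray, np.ndarray]:
        Pa = self.C[0][:, : self.n_occ[0]] @ self.C[0][:, : self.n_occ[0]].T
        Pb = self.C[1][:, : self.n_occ[1]] @ self.C[1][:, : self.n_occ[1]].T
        return Pa, Pb


def _jk(eri, P):
    J = np.einsum("mnls,ls->mn", eri, P, optimize=True)
    K = np.einsum("mlns,ls->mn", eri, P, optimize=True)
    return J, K


def _uhf_energy(h, Fa, Fb, Pa, Pb, enuc):
    return 0.5 * (
        np.einsum("mn,mn->", Pa + Pb, h)
        + np.einsum("mn,mn->", Pa, Fa)
        + np.einsum("mn,mn->", Pb, Fb)
    ) + enuc


def solve_scf(
    geometry: FragmentedGeometry,
    basis_name: str,
    kind: str = "UHF",
    scf_conv: float = 1e-9,
    maxiter: int = 300,
    ao: AOIntegralSet | None = None,
    guess: tuple[np.ndarray, np.ndarray] | None = None,
    guess_density: tuple[np.ndarray, np.ndarray] | None = None,
) -> SCFSolution:
    """Converge a UHF or ROHF determinant for the geometry.

    ``guess`` seeds with MO coefficients, ``guess_density`` with AO
    spin densities (e.g. a fragment superposition, which keeps the
    electron assignment between fragments correct and avoids spurious
    charge-transfer solutions of the bare core guess).  A plain DIIS
    run is tried first; if it oscillates (open-shell degeneracies such
    as a halogen p hole are the usual culprits) the solver retries with
    a level shift and heavier density damping before giving up.  Raises
    SCFError (with the iteration history) on final non-convergence.
    """
    kind = kind.upper()
    if kind not in ("UHF", "ROHF"):
        raise ValueError("kind must be UHF or ROHF")
    if ao is None:
        ao = build_ao_integrals(geometry, basis_name)
    na, nb = geometry.n_alpha, geometry.n_beta
    if na < nb:
        raise SCFError("alpha must be the majority spin (multiplicity sign)")
    attempts = [
        dict(level_shift=0.0, damp_iters=3, damp=0.5),
        dict(level_shift=0.3, damp_iters=12, damp=0.7),
        dict(level_shift=1.0, damp_iters=30, damp=0.8),
    ]
    last_exc = None
    for att in attempts:
        try:
            return _scf_loop(
                geometry, kind, ao, na, nb, scf_conv, maxiter, guess,
                guess_density, **att
            )
        except SCFError as exc:
            last_exc = exc
    raise last_exc


def _scf_loop(
    geometry, kind, ao, na, nb, scf_conv, maxiter, guess, guess_density=None,
    level_shift=0.0, damp_iters=3, damp=0.5,
):
    S, h, eri = ao.overlap, ao.hcore, ao.eri
    X = _lowdin_x(S)
    if guess_density is not None:
        Pa, Pb = guess_density
        # one Fock diagonalization turns the density guess into orbitals
        Ja, Ka = _jk(eri, Pa)
        Jb, Kb = _jk(eri, Pb)
        _, Ca = sla.eigh(h + Ja + Jb - Ka, S)
        _, Cb = sla.eigh(h + Ja + Jb - Kb, S)
    else:
        if guess is not None:
            Ca, Cb = guess
        else:
            e, c = sla.eigh(h, S)
            Ca = Cb = c
        Pa = Ca[:, :na] @ Ca[:, :na].T
        Pb = Cb[:, :nb] @ Cb[:, :nb].T

    diis_F, diis_E = [], []
    history = []
    e_old = None
    for it in range(1, maxiter + 1):
        Ja, Ka = _jk(eri, Pa)
        Jb, Kb = _jk(eri, Pb)
        Fa = h + Ja + Jb - Ka
        Fb = h + Ja + Jb - Kb
        energy = _uhf_energy(h, Fa, Fb, Pa, Pb, ao.e_nuclear)

        # shift virtual levels up: F += shift * (S - S P S) per spin
        shift = level_shift if it <= max(damp_iters * 4, 40) else 0.0
        Fa_it = Fa + shift * (S - S @ Pa @ S) if shift else Fa
        Fb_it = Fb + shift * (S - S @ Pb @ S) if shift else Fb

        if kind == "UHF":
            err = np.concatenate(
                [
                    (X.T @ (F @ P @ S - S @ P @ F) @ X).ravel()
                    for F, P in ((Fa, Pa), (Fb, Pb))
                ]
            )
            Fa_eff, Fb_eff = _diis_step(diis_F, diis_E, [Fa_it, Fb_it], err)
            ea, Ca = sla.eigh(Fa_eff, S)
            eb, Cb = sla.eigh(Fb_eff, S)
        else:
            Feff = _rohf_effective_fock(Fa_it, Fb_it, Ca, S, na, nb)
            P = 0.5 * (Pa + Pb)
            err = (X.T @ (Feff @ P @ S - S @ P @ Feff) @ X).ravel()
            (Feff,) = _diis_step(diis_F, diis_E, [Feff], err)
            ea, Ca = sla.eigh(Feff, S)
            eb, Cb = ea.copy(), Ca

        grad = float(np.max(np.abs(err)))
        history.append((it, energy, grad))
        Pa_new = Ca[:, :na] @ Ca[:, :na].T
        Pb_new = Cb[:, :nb] @ Cb[:, :nb].T
        dP = max(np.max(np.abs(Pa_new - Pa)), np.max(np.abs(Pb_new - Pb)))
        if it <= damp_iters and guess is None and guess_density is None:
            Pa = damp * Pa_new + (1 - damp) * Pa
            Pb = damp * Pb_new + (1 - damp) * Pb
        else:
            Pa, Pb = Pa_new, Pb_new
        if (
            e_old is not None
            and shift == 0.0
            and abs(energy - e_old) < scf_conv
            and dP < max(1e-7, scf_conv * 100)
            and grad < 1e-6
        ):
            return SCFSolution(
                kind=kind, energy=energy, C=(Ca, Cb), eps=(ea, eb),
                fock_ao=(Fa, Fb), n_occ=(na, nb), converged=True,
                n_iter=it, ao=ao,
            )
        e_old = energy
    raise SCFError(
        f"SCF ({kind}) did not converge in {maxiter} cycles "
        f"(last dE history tail: {[f'{h[1]:.10f}' for h in history[-3:]]})",
        history,
    )


def _lowdin_x(S):
    e, v = np.linalg.eigh(S)
    if e.min() < 1e-9:
        keep = e > 1e-9
        e, v = e[keep], v[:, keep]
    return v / np.sqrt(e)


def _diis_step(diis_F, diis_E, focks, err, max_vec=10):
    diis_F.append([F.copy() for F in focks])
    diis_E.append(err.copy())
    if len(diis_E) > max_vec:
        diis_F.pop(0)
        diis_E.pop(0)
    n = len(diis_E)
    if n < 2:
        return focks
    B = -np.ones((n + 1, n + 1))
    B[n, n] = 0.0
    for i in range(n):
        for j in range(n):
            B[i, j] = diis_E[i] @ diis_E[j]
    rhs = np.zeros(n + 1)
    rhs[n] = -1.0
    try:
        c = np.linalg.solve(B, rhs)[:n]
    except np.linalg.LinAlgError:
        return focks
    out = []
    for k in range(len(focks)):
        F = np.zeros_like(focks[k])
        for i in range(n):
            F += c[i] * diis_F[i][k]
        out.append(F)
    return out


def _rohf_effective_fock(Fa, Fb, C, S, na, nb):
    """Roothaan effective Fock in the AO basis.

    Blocks in the current MO basis (c = doubly occupied, o = singly
    occupied, v = virtual): diagonal blocks take (Fa+Fb)/2; the
    closed-open coupling is Fb, open-virtual is Fa, closed-virtual is
    the average.
    """
    Fa_mo = C.T @ Fa @ C
    Fb_mo = C.T @ Fb @ C
    avg = 0.5 * (Fa_mo + Fb_mo)
    n = C.shape[1]
    Feff = avg.copy()
    c = slice(0, nb)
    o = slice(nb, na)
    v = slice(na, n)
    Feff[c, o] = Fb_mo[c, o]
    Feff[o, c] = Fb_mo[o, c]
    Feff[o, v] = Fa_mo[o, v]
    Feff[v, o] = Fa_mo[v, o]
    # back to AO: F_ao = S C Feff C^T S  (C^T S C = 1)
    SC = S @ C
    return SC @ Feff @ SC.T
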