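"""Pair-restricted unrestricted CCSD in the spin-orbital basis.

Doubles amplitudes are solved only for a caller-specified set of
occupied pairs (the interfragment strong pairs in HFLD; all pairs in
oracle/full mode); all other doubles are pinned at zero and their
residuals ignored.  Singles are kept for every occupied orbital by
default.  The residual equations are the standard factorized
spin-orbital CCSD equations with the full (non-diagonal) Fock matrix:
off-diagonal occupied couplings appear because the occupied space is
localized, and occupied-virtual blocks F_ia appear for restricted
open-shell references that do not satisfy Brillouin's theorem.  The
diagonal Fock elements supply the update denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .localization import PairRecord
from .mospace import CorrelationSpace


class CCConvergenceError(RuntimeError):
    def __init__(self, msg, history=None):
        super().__init__(msg)
        self.history = history or []


@dataclass
class AmplitudeSet:
    """Converged singles and (pair-restricted) doubles amplitudes.

    ``t2[i, j, a, b]`` is antisymmetric in (i, j) and (a, b); rows for
    pairs outside the active set are identically zero.
    """

    t1: np.ndarray           # (nocc, nvirt)
    t2: np.ndarray           # (nocc, nocc, nvirt, nvirt)
    pair_mask: np.ndarray    # (nocc, nocc) bool, symmetric, False diagonal

    def tau(self) -> np.ndarray:
        """tau_ijab = t2 + t1_ia t1_jb - t1_ib t1_ja."""
        t1t1 = np.einsum("ia,jb->ijab", self.t1, self.t1)
        return self.t2 + t1t1 - t1t1.transpose(0, 1, 3, 2)


@dataclass
class CCResult:
    amplitudes: AmplitudeSet
    e_singles: float
    pair_energies: dict[tuple[int, int], float]   # spin-orbital (i<j) -> eps
    e_corr: float
    converged: bool
    iterations: list[tuple[int, float, float, float]]  # it, E, dE, rms

    @property
    def e_pairs(self) -> float:
        return sum(self.pair_energies.values())


def pair_mask_from_records(
    space: CorrelationSpace, active_pairs: list[PairRecord] | None
) -> np.ndarray:
    """Boolean (nocc, nocc) mask of active doubles rows; None = all pairs."""
    o = space.nocc
    mask = np.zeros((o, o), dtype=bool)
    if active_pairs is None:
        mask[:, :] = True
        np.fill_diagonal(mask, False)
        return mask
    for p in active_pairs:
        i, j = space.so_indices(p)
        mask[i, j] = mask[j, i] = True
    return mask


def pair_energies(t1, t2, A_oovv) -> dict[tuple[int, int], float]:
    """eps_ij = 1/2 sum_ab <ij||ab> tau_ijab for i < j.

    Summing over pairs and adding the singles energy recovers the total
    correlation energy exactly (bookkeeping identity).
    """
    t1t1 = np.einsum("ia,jb->ijab", t1, t1)
    tau = t2 + t1t1 - t1t1.transpose(0, 1, 3, 2)
    e_mat = 0.5 * np.einsum("ijab,ijab->ij", A_oovv, tau, optimize=True)
    o = t1.shape[0]
    # e_mat[i,j] == e_mat[j,i] by antisymmetry; each unordered pair counted once
    return {
        (i, j): float(e_mat[i, j]) for i in range(o) for j in range(i + 1, o)
    }


def solve_pair_restricted_uccsd(
    space: CorrelationSpace,
    active_pairs: list[PairRecord] | None,
    cc_conv: float = 1e-8,
    maxiter: int = 200,
    keep_all_singles: bool = True,
    diis_size: int = 8,
    rms_conv: float | None = None,
) -> CCResult:
    """Solve the CCSD amplitude equations on the active pair set.

    ``active_pairs=None`` activates every pair (full CCSD).  With
    ``keep_all_singles=False``, singles are restricted to occupied
    orbitals that appear in at least one active pair.  Convergence
    needs |dE| < cc_conv and an amplitude-step RMS below ``rms_conv``
    (default 10 * cc_conv).
    """
    if rms_conv is None:
        rms_conv = 10.0 * cc_conv
    o, v = space.nocc, space.nvirt
    A = space.eri_anti
    f = space.fock
    mask = pair_mask_from_records(space, active_pairs)
    m4 = mask[:, :, None, None]

    oo = slice(0, o)
    vv = slice(o, o + v)
    f_oo = f[oo, oo]
    f_ov = f[oo, vv]
    f_vv = f[vv, vv]
    d_o = np.diag(f)[:o]
    d_v = np.diag(f)[o:]
    D1 = d_o[:, None] - d_v[None, :]
    D2 = d_o[:, None, None, None] + d_o[None, :, None, None] \
        - d_v[None, None, :, None] - d_v[None, None, None, :]
    if np.min(np.abs(D2)) < 1e-8:
        raise CCConvergenceError("vanishing doubles denominator (orbital degeneracy)")
    # off-diagonal Fock blocks (diagonals live in the denominators)
    fp_oo = f_oo - np.diag(d_o)
    fp_vv = f_vv - np.diag(d_v)

    # integral blocks <pq||rs>, sliced directly (no index gymnastics)
    oooo = A[oo, oo, oo, oo]    # <mn||ij>
    ooov = A[oo, oo, oo, vv]    # <mn||ie>
    oovo = A[oo, oo, vv, oo]    # <nm||ei>
    oovv = A[oo, oo, vv, vv]    # <mn||ef>
    ovov = A[oo, vv, oo, vv]    # <na||if>
    ovvo = A[oo, vv, vv, oo]    # <mb||ej>
    ovoo = A[oo, vv, oo, oo]    # <mb||ij>
    ovvv = A[oo, vv, vv, vv]    # <ma||ef>
    vvvo = A[vv, vv, vv, oo]    # <ab||ej>
    vvvv = A[vv, vv, vv, vv]    # <ab||ef>

    if keep_all_singles:
        s_mask = np.ones(o, dtype=bool)
    else:
        s_mask = mask.any(axis=1)

    # MP2-type initial guess (semicanonical)
    t1 = (f_ov / D1) * s_mask[:, None]
    t2 = (oovv / D2) * m4

    def energy(t1, t2):
        e_s = float(np.einsum("ia,ia->", f_ov, t1))
        e_d = 0.25 * float(np.einsum("ijab,ijab->", oovv, t2, optimize=True))
        e_ss = 0.5 * float(
            np.einsum("ijab,ia,jb->", oovv, t1, t1, optimize=True)
        )
        return e_s + e_d + e_ss

    diis_t, diis_e = [], []
    e_old = energy(t1, t2)
    history = []
    converged = False
    for it in range(1, maxiter + 1):
        t1t1 = np.einsum("ia,jb->ijab", t1, t1)
        tau_t = t2 + 0.5 * (t1t1 - t1t1.transpose(0, 1, 3, 2))
        tau = t2 + t1t1 - t1t1.transpose(0, 1, 3, 2)

        # one-particle intermediates
        Fae = fp_vv - 0.5 * np.einsum("me,ma->ae", f_ov, t1) \
            + np.einsum("mf,mafe->ae", t1, ovvv, optimize=True) \
            - 0.5 * np.einsum("mnaf,mnef->ae", tau_t, oovv, optimize=True)
        Fmi = fp_oo + 0.5 * np.einsum("me,ie->mi", f_ov, t1) \
            + np.einsum("ne,mnie->mi", t1, ooov, optimize=True) \
            + 0.5 * np.einsum("inef,mnef->mi", tau_t, oovv, optimize=True)
        Fme = f_ov + np.einsum("nf,mnef->me", t1, oovv, optimize=True)

        # two-particle intermediates
        Wmnij = oooo \
            + np.einsum("je,mnie->mnij", t1, ooov, optimize=True) \
            - np.einsum("ie,mnje->mnij", t1, ooov, optimize=True) \
            + 0.25 * np.einsum("ijef,mnef->mnij", tau, oovv, optimize=True)
        Wabef = vvvv \
            + np.einsum("mb,maef->abef", t1, ovvv, optimize=True) \
            - np.einsum("ma,mbef->abef", t1, ovvv, optimize=True) \
            + 0.25 * np.einsum("mnab,mnef->abef", tau, oovv, optimize=True)
        Wmbej = ovvo \
            + np.einsum("jf,mbef->mbej", t1, ovvv, optimize=True) \
            - np.einsum("nb,mnej->mbej", t1, oovo, optimize=True) \
            - np.einsum("jnfb,mnef->mbej",
                        0.5 * t2 + np.einsum("jf,nb->jnfb", t1, t1),
                        oovv, optimize=True)

        # T1 residual (diagonal Fock lives in the denominators)
        rhs1 = f_ov.copy()
        rhs1 += np.einsum("ie,ae->ia", t1, Fae, optimize=True)
        rhs1 -= np.einsum("ma,mi->ia", t1, Fmi, optimize=True)
        rhs1 += np.einsum("imae,me->ia", t2, Fme, optimize=True)
        rhs1 -= np.einsum("nf,naif->ia", t1, ovov, optimize=True)
        rhs1 -= 0.5 * np.einsum("imef,maef->ia", t2, ovvv, optimize=True)
        rhs1 -= 0.5 * np.einsum("mnae,nmei->ia", t2, oovo, optimize=True)

        # T2 residual
        Ftmp_vv = Fae - 0.5 * np.einsum("mb,me->be", t1, Fme)
        Ftmp_oo = Fmi + 0.5 * np.einsum("je,me->mj", t1, Fme)
        rhs2 = oovv.copy()
        x = np.einsum("ijae,be->ijab", t2, Ftmp_vv, optimize=True)
        rhs2 += x - x.transpose(0, 1, 3, 2)
        x = np.einsum("imab,mj->ijab", t2, Ftmp_oo, optimize=True)
        rhs2 -= x - x.transpose(1, 0, 2, 3)
        rhs2 += 0.5 * np.einsum("mnab,mnij->ijab", tau, Wmnij, optimize=True)
        rhs2 += 0.5 * np.einsum("ijef,abef->ijab", tau, Wabef, optimize=True)
        x = np.einsum("imae,mbej->ijab", t2, Wmbej, optimize=True)
        x -= np.einsum("ie,ma,mbej->ijab", t1, t1, ovvo, optimize=True)
        rhs2 += x - x.transpose(1, 0, 2, 3) - x.transpose(0, 1, 3, 2) \
            + x.transpose(1, 0, 3, 2)
        x = np.einsum("ie,abej->ijab", t1, vvvo, optimize=True)
        rhs2 += x - x.transpose(1, 0, 2, 3)
        x = np.einsum("ma,mbij->ijab", t1, ovoo, optimize=True)
        rhs2 -= x - x.transpose(0, 1, 3, 2)

        t1_new = (rhs1 / D1) * s_mask[:, None]
        t2_new = (rhs2 / D2) * m4

        # DIIS on the amplitude step
        err = np.concatenate([(t1_new - t1).ravel(), (t2_new - t2).ravel()])
        rms = float(np.sqrt(np.mean(err ** 2)))
        vec = np.concatenate([t1_new.ravel(), t2_new.ravel()])
        diis_t.append(vec)
        diis_e.append(err)
        if len(diis_t) > diis_size:
            diis_t.pop(0)
            diis_e.pop(0)
        if len(diis_t) >= 2:
            n = len(diis_t)
            B = -np.ones((n + 1, n + 1))
            B[n, n] = 0.0
            for a in range(n):
                for b in range(n):
                    B[a, b] = diis_e[a] @ diis_e[b]
            rhs = np.zeros(n + 1)
            rhs[n] = -1.0
            try:
                c = np.linalg.solve(B, rhs)[:n]
                vec = sum(ci * vi for ci, vi in zip(c, diis_t))
            except np.linalg.LinAlgError:
                pass
        t1 = vec[: o * v].reshape(o, v) * s_mask[:, None]
        t2 = vec[o * v :].reshape(o, o, v, v) * m4

        e_new = energy(t1, t2)
        de = e_new - e_old
        history.append((it, e_new, de, rms))
        e_old = e_new
        if abs(de) < cc_conv and rms < rms_conv:
            converged = True
            break
    if not converged:
        raise CCConvergenceError(
            f"CCSD did not converge in {maxiter} iterations "
            f"(last |dE|={abs(history[-1][2]):.2e}, rms={history[-1][3]:.2e})",
            history,
        )

    amp = AmplitudeSet(t1=t1, t2=t2, pair_mask=mask)
    eps = pair_energies(t1, t2, oovv)
    e_singles = float(np.einsum("ia,ia->", f_ov, t1))
    e_corr = e_singles + sum(eps.values())
    return CCResult(
        amplitudes=amp,
        e_singles=e_singles,
        pair_energies=eps,
        e_corr=e_corr,
        converged=True,
        iterations=history,
    )
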