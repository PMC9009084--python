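"""Foster-Boys localization, fragment assignment and pair enumeration.

Occupied orbitals (per spin, excluding the frozen core) and virtual
orbitals (per spin, the canonical-orbital stand-in for pair natural
orbitals) are localized by maximizing the Boys objective
sum_i |<i|r|i>|^2 with deterministic Jacobi sweeps.  Localized orbitals
are then assigned to the fragment carrying the larger Mulliken (or
Lowdin) population, and occupied spin pairs are enumerated with their
intra-/interfragment class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

log = logging.getLogger("hfld")


class LocalizationError(RuntimeError):
    pass


@dataclass
class LocalizedBlock:
    """One localized orbital block (one spin, one space)."""

    coeff: np.ndarray        # AO x n_loc
    unitary: np.ndarray      # canonical -> localized transform
    objective: float
    sweeps: int


def foster_boys_localize(
    coeff_block: np.ndarray,
    dipole_ao: np.ndarray,
    loc_conv: float = 1e-6,
    max_sweeps: int = 400,
) -> LocalizedBlock:
    """Maximize the Boys objective over 2x2 Jacobi rotations.

    Pair ordering is fixed (ascending i<j), making the result
    deterministic for a given input; the objective is monotonically
    non-decreasing by construction and a decrease raises an error.
    """
    C = np.array(coeff_block, dtype=float, copy=True)
    n = C.shape[1]
    U = np.eye(n)
    if n < 2:
        obj = 0.0
        if n == 1:
            r = np.array([C[:, 0] @ dipole_ao[d] @ C[:, 0] for d in range(3)])
            obj = float(r @ r)
        return LocalizedBlock(coeff=C, unitary=U, objective=obj, sweeps=0)

    # dipole matrices in the current MO basis, updated in place
    R = np.stack([C.T @ dipole_ao[d] @ C for d in range(3)])
    objective = float(np.sum(np.einsum("dii->di", R) ** 2))
    sweeps = 0
    while sweeps < max_sweeps:
        sweeps += 1
        max_gain = 0.0
        for i in range(n - 1):
            for j in range(i + 1, n):
                rii = R[:, i, i]
                rjj = R[:, j, j]
                rij = R[:, i, j]
                A = float(rij @ rij - 0.25 * (rii - rjj) @ (rii - rjj))
                B = float(rij @ (rii - rjj))
                gain = A + np.hypot(A, B)
                if gain <= 1e-15:
                    continue
                gamma = 0.25 * np.arctan2(B, -A)
                c, s = np.cos(gamma), np.sin(gamma)
                for M in (R[0], R[1], R[2]):
                    ri = M[:, i].copy()
                    rj = M[:, j].copy()
                    M[:, i] = c * ri + s * rj
                    M[:, j] = -s * ri + c * rj
                    ri = M[i, :].copy()
                    rj = M[j, :].copy()
                    M[i, :] = c * ri + s * rj
                    M[j, :] = -s * ri + c * rj
                for M in (C, U):
                    ri = M[:, i].copy()
                    rj = M[:, j].copy()
                    M[:, i] = c * ri + s * rj
                    M[:, j] = -s * ri + c * rj
                max_gain = max(max_gain, gain)
        new_obj = float(np.sum(np.einsum("dii->di", R) ** 2))
        if new_obj < objective - 1e-9:
            raise LocalizationError(
                f"Boys objective decreased: {objective} -> {new_obj}"
            )
        objective = new_obj
        if max_gain < loc_conv:
            break
    else:
        log.warning("Boys localization hit max_sweeps=%d", max_sweeps)
    return LocalizedBlock(coeff=C, unitary=U, objective=objective, sweeps=sweeps)


@dataclass
class FragmentAssignment:
    """Fragment label and populations per localized orbital."""

    labels: list[str]                    # "X" or "Y" per orbital
    populations: np.ndarray              # (n_orb, 2) populations on X, Y

    def indices_of(self, fragment: str) -> list[int]:
        return [k for k, lab in enumerate(self.labels) if lab == fragment]


def assign_to_fragments(
    coeff: np.ndarray,
    overlap: np.ndarray,
    ao_fragment_x: np.ndarray,
    scheme: str = "mulliken",
) -> FragmentAssignment:
    """Assign each orbital to the fragment with the larger population.

    Mulliken: q_F(i) = sum_{mu in F} C_mu_i (S C)_mu_i.  Lowdin uses
    (S^1/2 C)^2 instead (more robust with diffuse functions).  Exact
    50/50 ties go to fragment X (deterministic, logged).
    """
    if scheme == "mulliken":
        w = coeff * (overlap @ coeff)
    elif scheme == "lowdin":
        sh = sla.sqrtm(overlap).real
        w = (sh @ coeff) ** 2
    else:
        raise ValueError(f"unknown population scheme {scheme!r}")
    qx = w[ao_fragment_x].sum(axis=0)
    qy = w[~ao_fragment_x].sum(axis=0)
    labels = []
    for k in range(coeff.shape[1]):
        if abs(qx[k] - qy[k]) < 1e-12:
            log.warning("orbital %d populations tie (%.6f); assigning to X", k, qx[k])
            labels.append("X")
        else:
            labels.append("X" if qx[k] > qy[k] else "Y")
    return FragmentAssignment(labels=labels, populations=np.stack([qx, qy], axis=1))


# -- pair enumeration -------------------------------------------------------

@dataclass(frozen=True)
class PairRecord:
    """One occupied spin pair.

    ``spin_case`` is "aa", "bb" or "ab"; ``i``/``j`` index correlated
    occupied orbitals within their spin set (i < j for same spin; for
    "ab", i is the alpha and j the beta index).
    """

    spin_case: str
    i: int
    j: int
    fragment_class: str      # "intra-X", "intra-Y" or "inter"

    @property
    def is_interfragment(self) -> bool:
        return self.fragment_class == "inter"


@dataclass
class PairList:
    pairs: list[PairRecord]

    def __iter__(self):
        return iter(self.pairs)

    def __len__(self):
        return len(self.pairs)

    def count(self, spin_case: str | None = None, fragment_class: str | None = None):
        return sum(
            1
            for p in self.pairs
            if (spin_case is None or p.spin_case == spin_case)
            and (fragment_class is None or p.fragment_class == fragment_class)
        )

    @property
    def interfragment(self) -> list[PairRecord]:
        return [p for p in self.pairs if p.is_interfragment]


def _pair_class(fi: str, fj: str) -> str:
    if fi == fj:
        return f"intra-{fi}"
    return "inter"


def enumerate_pairs(occ_frag_alpha: list[str], occ_frag_beta: list[str]) -> PairList:
    """All correlated occupied spin pairs with their fragment class.

    Counts: C(n_a,2) alpha-alpha, C(n_b,2) beta-beta, n_a*n_b
    alpha-beta pairs (frozen core excluded upstream).
    """
    pairs = []
    na, nb = len(occ_frag_alpha), len(occ_frag_beta)
    for i in range(na):
        for j in range(i + 1, na):
            pairs.append(
                PairRecord("aa", i, j, _pair_class(occ_frag_alpha[i], occ_frag_alpha[j]))
            )
    for i in range(nb):
        for j in range(i + 1, nb):
            pairs.append(
                PairRecord("bb", i, j, _pair_class(occ_frag_beta[i], occ_frag_beta[j]))
            )
    for i in range(na):
        for j in range(nb):
            pairs.append(
                PairRecord("ab", i, j, _pair_class(occ_frag_alpha[i], occ_frag_beta[j]))
            )
    return PairList(pairs)
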