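"""Brute-force determinant-space oracles: FCI and dense CCSD.

Both oracles work directly in the basis of Slater determinants using
Slater-Condon rules, which makes them completely independent of the
factorized amplitude equations of the main solver (they share only the
integral tensors).

The CCSD oracle parameterizes the wave function as e^T|0> with T
truncated at singles and doubles, builds e^T|0> explicitly in the full
determinant space (the exponential terminates because T is nilpotent),
and iterates the projected equations <mu|(H - E) e^T|0> = 0 for every
single and double excitation mu.  At convergence this is exactly CCSD.
Sizes are capped: these are desk-scale reference implementations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .mospace import CorrelationSpace


class OracleSizeError(ValueError):
    pass


def _effective_h1(space: CorrelationSpace) -> np.ndarray:
    """One-electron part in the correlated window.

    The Fock matrix contains the mean field of all occupied orbitals
    (frozen core included); subtracting the mean field of the
    correlated occupieds leaves h_core + frozen-core field.  The
    unknown constant (core energy) cancels in correlation energies.
    """
    f = space.fock
    A = space.eri_anti
    occ = range(space.nocc)
    h = f.copy()
    for i in occ:
        h -= A[:, i, :, i]
    return h


@dataclass
class _DetSpace:
    dets: list[tuple[int, ...]]          # sorted spin-orbital occupations
    index: dict[tuple[int, ...], int]


def _build_space(space: CorrelationSpace) -> _DetSpace:
    noa, nob = space.n_occ
    nva, nvb = space.n_virt
    o = space.nocc
    alphas = [i for i in range(space.nso) if space.spin[i] == 0]
    betas = [i for i in range(space.nso) if space.spin[i] == 1]
    dets = []
    for occ_a in itertools.combinations(alphas, noa):
        for occ_b in itertools.combinations(betas, nob):
            dets.append(tuple(sorted(occ_a + occ_b)))
    # reference determinant first
    ref = tuple(range(o))
    dets.sort(key=lambda d: (d != ref, d))
    return _DetSpace(dets=dets, index={d: k for k, d in enumerate(dets)})


def _phase_annihilate(det: tuple, orb: int) -> int:
    return (-1) ** det.index(orb)


def _apply_excitation(det: tuple, holes: tuple, parts: tuple):
    """Apply a_p1^+ ... a_h1 ... in normal order; None if vanishing."""
    occ = list(det)
    sign = 1
    for h in reversed(holes):        # annihilate h_n ... h_1
        if h not in occ:
            return None, 0
        sign *= (-1) ** occ.index(h)
        occ.remove(h)
    for p in reversed(parts):        # then create p_n ... p_1
        if p in occ:
            return None, 0
        k = int(np.searchsorted(occ, p))
        sign *= (-1) ** k
        occ.insert(k, p)
    return tuple(occ), sign


def _excitation_degree(d1: tuple, d2: tuple) -> int:
    return len(set(d1) - set(d2))


def _sc_element(d1, d2, h1, A) -> float:
    """Slater-Condon matrix element <d1|H|d2>."""
    s1, s2 = set(d1), set(d2)
    diff1 = sorted(s1 - s2)
    diff2 = sorted(s2 - s1)
    deg = len(diff1)
    if deg > 2:
        return 0.0
    if deg == 0:
        e = sum(h1[i, i] for i in d1)
        e += 0.5 * sum(A[i, j, i, j] for i in d1 for j in d1)
        return e
    if deg == 1:
        (i,), (a,) = diff1, diff2
        common = s1 & s2
        val = h1[i, a] + sum(A[i, j, a, j] for j in common)
        # phase: align both determinants
        perm = _phase_annihilate(d1, i) * _phase_annihilate(d2, a)
        return perm * val
    (i, j), (a, b) = diff1, diff2
    val = A[i, j, a, b]
    perm = (
        _phase_annihilate(d1, i)
        * _phase_annihilate(tuple(x for x in d1 if x != i), j)
        * _phase_annihilate(d2, a)
        * _phase_annihilate(tuple(x for x in d2 if x != a), b)
    )
    return perm * val


def _hamiltonian(space: CorrelationSpace, ds: _DetSpace) -> np.ndarray:
    """Dense H in the determinant basis via connected excitations."""
    h1 = _effective_h1(space)
    A = space.eri_anti
    n = len(ds.dets)
    H = np.zeros((n, n))
    alphas = [i for i in range(space.nso) if space.spin[i] == 0]
    betas = [i for i in range(space.nso) if space.spin[i] == 1]
    for k, det in enumerate(ds.dets):
        occ = set(det)
        H[k, k] = _sc_element(det, det, h1, A)
        # connected singles and doubles (spin-conserving)
        occ_a = [i for i in det if space.spin[i] == 0]
        occ_b = [i for i in det if space.spin[i] == 1]
        vir_a = [a for a in alphas if a not in occ]
        vir_b = [b for b in betas if b not in occ]
        singles = [(i, a) for i in occ_a for a in vir_a] + [
            (i, a) for i in occ_b for a in vir_b
        ]
        for i, a in singles:
            d2, sgn = _apply_excitation(det, (i,), (a,))
            m = ds.index[d2]
            if m > k:
                val = _sc_element(d2, det, h1, A)
                H[m, k] = val
                H[k, m] = val
        doubles = (
            [(p, q) for p, q in itertools.combinations(occ_a, 2)]
            + [(p, q) for p, q in itertools.combinations(occ_b, 2)]
            + [(p, q) for p in occ_a for q in occ_b]
        )
        virt_pairs_a = list(itertools.combinations(vir_a, 2))
        virt_pairs_b = list(itertools.combinations(vir_b, 2))
        virt_pairs_ab = [(a, b) for a in vir_a for b in vir_b]
        for i, j in doubles:
            si, sj = space.spin[i], space.spin[j]
            if si == sj:
                vps = virt_pairs_a if si == 0 else virt_pairs_b
            else:
                vps = virt_pairs_ab
            for a, b in vps:
                d2, sgn = _apply_excitation(det, (i, j), (a, b))
                if d2 is None:
                    continue
                m = ds.index[d2]
                if m > k:
                    val = _sc_element(d2, det, h1, A)
                    H[m, k] = val
                    H[k, m] = val
    return H


def fci_oracle(space: CorrelationSpace, max_spatial: int = 8) -> float:
    """Exact correlation energy by diagonalization in the determinant basis.

    Returns E_FCI - <0|H|0> for the given correlated window (frozen
    core respected).  Capped at ``max_spatial`` spatial orbitals.
    """
    n_spatial = (space.nso + 1) // 2
    if n_spatial > max_spatial:
        raise OracleSizeError(
            f"FCI oracle capped at {max_spatial} spatial orbitals, got {n_spatial}"
        )
    ds = _build_space(space)
    H = _hamiltonian(space, ds)
    w = np.linalg.eigvalsh(H)
    return float(w[0] - H[0, 0])


def dense_uccsd_oracle(
    space: CorrelationSpace,
    max_so: int = 24,
    conv: float = 1e-11,
    maxiter: int = 300,
) -> float:
    """CCSD correlation energy via the determinant-space exponential ansatz."""
    if space.nso > max_so:
        raise OracleSizeError(
            f"CCSD oracle capped at {max_so} spin orbitals, got {space.nso}"
        )
    ds = _build_space(space)
    H = _hamiltonian(space, ds)
    ndet = len(ds.dets)
    ref = ds.dets[0]
    o = space.nocc

    # excitation list: amplitude index -> (holes, parts); denominators
    d_orb = np.diag(space.fock)
    excitations = []
    occ_a = [i for i in ref if space.spin[i] == 0]
    occ_b = [i for i in ref if space.spin[i] == 1]
    vir = [a for a in range(space.nso) if a not in ref]
    vir_a = [a for a in vir if space.spin[a] == 0]
    vir_b = [a for a in vir if space.spin[a] == 1]
    for i in occ_a:
        for a in vir_a:
            excitations.append(((i,), (a,)))
    for i in occ_b:
        for a in vir_b:
            excitations.append(((i,), (a,)))
    for (i, j) in (
        list(itertools.combinations(occ_a, 2))
        + list(itertools.combinations(occ_b, 2))
        + [(p, q) for p in occ_a for q in occ_b]
    ):
        si, sj = space.spin[i], space.spin[j]
        if si == sj:
            vps = (
                itertools.combinations(vir_a, 2)
                if si == 0
                else itertools.combinations(vir_b, 2)
            )
        else:
            vps = ((a, b) for a in vir_a for b in vir_b)
        for a, b in vps:
            excitations.append(((i, j), (a, b)))
    namp = len(excitations)
    denom = np.array(
        [sum(d_orb[h] for h in hs) - sum(d_orb[p] for p in ps) for hs, ps in excitations]
    )
    # amplitude-indexed determinant of each excitation (phase +1 convention
    # relative to the operator application on the reference)
    amp_det = np.empty(namp, dtype=int)
    amp_phase = np.empty(namp)
    for k, (hs, ps) in enumerate(excitations):
        d2, sgn = _apply_excitation(ref, hs, ps)
        amp_det[k] = ds.index[d2]
        amp_phase[k] = sgn

    # sparse structure of the T operator: T[target, source] = phase * t[k]
    rows, cols, amp_ix, phases = [], [], [], []
    for src, det in enumerate(ds.dets):
        for k, (hs, ps) in enumerate(excitations):
            d2, sgn = _apply_excitation(det, hs, ps)
            if d2 is None:
                continue
            rows.append(ds.index[d2])
            cols.append(src)
            amp_ix.append(k)
            phases.append(sgn)
    if namp == 0:
        # no excitations available (e.g. high-spin minimal-basis systems)
        return 0.0
    rows = np.array(rows, dtype=int)
    cols = np.array(cols, dtype=int)
    amp_ix = np.array(amp_ix, dtype=int)
    phases = np.array(phases, dtype=float)

    t = np.zeros(namp)
    e0 = np.zeros(ndet)
    e0[0] = 1.0
    # MP2-like start
    t = np.array(
        [H[amp_det[k], 0] * amp_phase[k] / denom[k] for k in range(namp)]
    )
    e_old = 0.0
    for it in range(maxiter):
        T = sp.csr_matrix(
            (phases * t[amp_ix], (rows, cols)), shape=(ndet, ndet)
        )
        psi = e0.copy()
        term = e0.copy()
        for k in range(1, 20):
            term = T @ term / k
            psi += term
            if np.abs(term).max() < 1e-16:
                break
        hpsi = H @ psi
        e_corr = hpsi[0] - H[0, 0]
        # projected residuals on the amplitude determinants
        r_det = hpsi - (H[0, 0] + e_corr) * psi
        r = r_det[amp_det] * amp_phase
        t = t + r / denom
        if abs(e_corr - e_old) < conv and np.abs(r).max() < 1e-9:
            return float(e_corr)
        e_old = e_corr
    raise RuntimeError(
        f"determinant-space CCSD oracle did not converge (last E={e_corr})"
    )
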