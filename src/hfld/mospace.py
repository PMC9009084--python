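"""Correlated MO space: localized occupieds, canonical virtuals, and the
spin-orbital integral tensors used by screening, the CC solver and LED.

Spin-orbital ordering convention: alpha occupied, beta occupied, alpha
virtual, beta virtual.  Doubles amplitudes, pair lists and the
antisymmetrized integrals <pq||rs> (physicists' notation) all follow
this ordering.  The occupied space excludes the frozen core; virtuals
are the full canonical virtual block per spin (the untruncated-PNO
limit), with a Foster-Boys-localized copy kept for fragment assignment
of the dispersion excitations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .integrals import transform_mo
from .localization import (
    FragmentAssignment,
    PairList,
    assign_to_fragments,
    enumerate_pairs,
    foster_boys_localize,
)
from .reference import ReferenceState


@dataclass
class CorrelationSpace:
    """Everything the correlation treatment needs, in one place."""

    ref: ReferenceState
    # spatial orbital blocks (AO x n), occupieds localized, virtuals canonical
    occ_coeff: tuple[np.ndarray, np.ndarray]
    virt_coeff: tuple[np.ndarray, np.ndarray]
    # Foster-Boys-localized virtuals and the canonical->localized unitaries
    virt_loc_coeff: tuple[np.ndarray, np.ndarray]
    virt_unitary: tuple[np.ndarray, np.ndarray]
    occ_assignment: tuple[FragmentAssignment, FragmentAssignment]
    virt_assignment: tuple[FragmentAssignment, FragmentAssignment]
    pair_list: PairList
    # spin-orbital quantities
    fock: np.ndarray          # (nso, nso)
    eri_anti: np.ndarray      # <pq||rs>, (nso,)*4
    spin: np.ndarray          # 0 alpha / 1 beta per spin orbital
    n_occ: tuple[int, int]    # correlated occupied per spin
    n_virt: tuple[int, int]

    @property
    def nocc(self) -> int:
        return self.n_occ[0] + self.n_occ[1]

    @property
    def nvirt(self) -> int:
        return self.n_virt[0] + self.n_virt[1]

    @property
    def nso(self) -> int:
        return self.nocc + self.nvirt

    # fragment labels in spin-orbital occupied / virtual ordering
    @property
    def occ_frag(self) -> list[str]:
        return list(self.occ_assignment[0].labels) + list(self.occ_assignment[1].labels)

    @property
    def virt_frag(self) -> list[str]:
        return list(self.virt_assignment[0].labels) + list(self.virt_assignment[1].labels)

    def so_indices(self, pair) -> tuple[int, int]:
        """Spin-orbital occupied indices of a PairRecord."""
        noa = self.n_occ[0]
        if pair.spin_case == "aa":
            return pair.i, pair.j
        if pair.spin_case == "bb":
            return noa + pair.i, noa + pair.j
        return pair.i, noa + pair.j

    @property
    def virt_unitary_so(self) -> np.ndarray:
        """Block-diagonal canonical->localized rotation of the spin virtuals."""
        nva, nvb = self.n_virt
        U = np.zeros((nva + nvb, nva + nvb))
        U[:nva, :nva] = self.virt_unitary[0]
        U[nva:, nva:] = self.virt_unitary[1]
        return U


def build_correlation_space(
    ref: ReferenceState,
    loc_conv: float = 1e-6,
    population_scheme: str = "mulliken",
    localize_occupied: bool = True,
    localize_virtual: bool = True,
) -> CorrelationSpace:
    """Localize, assign, enumerate pairs and transform integrals.

    ``localize_occupied=False`` keeps canonical occupieds (used by the
    semicanonical-equals-canonical MP2 checks); fragment assignment is
    performed either way.
    """
    ao = ref.ao
    geom = ref.geometry
    nc = ref.n_frozen_core
    na, nb = ref.n_occ
    nao = ao.n_ao
    S = ao.overlap
    dip = ao.dipole
    frag_x = ao.basis.ao_fragment_mask("X")
    monomer = geom.is_monomer

    occ_blocks, virt_blocks, virt_loc, virt_U = [], [], [], []
    occ_assign, virt_assign = [], []
    for sp, nocc_sp in ((0, na), (1, nb)):
        C = ref.C[sp]
        occ = C[:, nc:nocc_sp]
        virt = C[:, nocc_sp:]
        if localize_occupied and not monomer:
            occ = foster_boys_localize(occ, dip, loc_conv).coeff
        if localize_virtual and not monomer:
            blk = foster_boys_localize(virt, dip, loc_conv)
            vloc, vU = blk.coeff, blk.unitary
        else:
            vloc, vU = virt.copy(), np.eye(virt.shape[1])
        occ_blocks.append(occ)
        virt_blocks.append(virt)
        virt_loc.append(vloc)
        virt_U.append(vU)
        occ_assign.append(assign_to_fragments(occ, S, frag_x, population_scheme))
        virt_assign.append(assign_to_fragments(vloc, S, frag_x, population_scheme))

    pair_list = enumerate_pairs(occ_assign[0].labels, occ_assign[1].labels)

    # spin-orbital Fock and antisymmetrized integrals
    Ma = np.hstack([occ_blocks[0], virt_blocks[0]])
    Mb = np.hstack([occ_blocks[1], virt_blocks[1]])
    Fa = Ma.T @ ref.fock_ao[0] @ Ma
    Fb = Mb.T @ ref.fock_ao[1] @ Mb
    # reuse the transformed tensor only when the full column sets coincide
    same_spatial = Ma.shape == Mb.shape and np.array_equal(Ma, Mb)
    g_aa = transform_mo(ao.eri, Ma, Ma, Ma, Ma)
    g_bb = g_aa if same_spatial else transform_mo(ao.eri, Mb, Mb, Mb, Mb)
    g_ab = g_aa if same_spatial else transform_mo(ao.eri, Ma, Ma, Mb, Mb)

    noa, nob = na - nc, nb - nc
    nva, nvb = nao - na, nao - nb
    nso = noa + nob + nva + nvb
    # spin-orbital index -> position within M_sigma
    ia = np.concatenate([np.arange(noa), noa + np.arange(nva)])
    ib = np.concatenate([np.arange(nob), nob + np.arange(nvb)])
    so_a = np.concatenate([np.arange(noa), noa + nob + np.arange(nva)])
    so_b = np.concatenate([noa + np.arange(nob), noa + nob + nva + np.arange(nvb)])

    G = np.zeros((nso, nso, nso, nso))
    G[np.ix_(so_a, so_a, so_a, so_a)] = g_aa[np.ix_(ia, ia, ia, ia)]
    G[np.ix_(so_b, so_b, so_b, so_b)] = g_bb[np.ix_(ib, ib, ib, ib)]
    G[np.ix_(so_a, so_a, so_b, so_b)] = g_ab[np.ix_(ia, ia, ib, ib)]
    G[np.ix_(so_b, so_b, so_a, so_a)] = g_ab[np.ix_(ia, ia, ib, ib)].transpose(2, 3, 0, 1)
    # <pq||rs> = (pr|qs) - (ps|qr)
    A = np.ascontiguousarray(G.transpose(0, 2, 1, 3))
    A -= G.transpose(0, 2, 3, 1)
    del G

    fock = np.zeros((nso, nso))
    fock[np.ix_(so_a, so_a)] = Fa[np.ix_(ia, ia)]
    fock[np.ix_(so_b, so_b)] = Fb[np.ix_(ib, ib)]
    spin = np.zeros(nso, dtype=int)
    spin[so_b] = 1

    return CorrelationSpace(
        ref=ref,
        occ_coeff=(occ_blocks[0], occ_blocks[1]),
        virt_coeff=(virt_blocks[0], virt_blocks[1]),
        virt_loc_coeff=(virt_loc[0], virt_loc[1]),
        virt_unitary=(virt_U[0], virt_U[1]),
        occ_assignment=(occ_assign[0], occ_assign[1]),
        virt_assignment=(virt_assign[0], virt_assign[1]),
        pair_list=pair_list,
        fock=fock,
        eri_anti=A,
        spin=spin,
        n_occ=(noa, nob),
        n_virt=(nva, nvb),
    )
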