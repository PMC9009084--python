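"""Semicanonical MP2 pair energies and strong/weak pair screening.

Pairs are split on |eps_pair^MP2| against T_CutPairs: strong pairs go
to the coupled-cluster solve, weak pairs stay at second order.  In the
HFLD assembly the interfragment weak-pair energy is added in full to
the strong-pair dispersion (interfragment weak pairs are essentially
dispersive); intrafragment pairs are dropped from the correlation
treatment and kept only as diagnostics.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .localization import PairRecord
from .mospace import CorrelationSpace


class ScreeningError(RuntimeError):
    pass


@dataclass(frozen=True)
class PairEnergy:
    pair: PairRecord
    energy: float      # semicanonical MP2 pair correlation energy, hartree


@dataclass
class ScreeningResult:
    pair_energies: list[PairEnergy]
    strength: list[str]            # "strong" / "weak", parallel to pair_energies
    t_cut_pairs: float

    @property
    def e_wp_inter(self) -> float:
        """Summed interfragment weak-pair energy (enters E_disp^C-CCSD)."""
        return sum(
            pe.energy
            for pe, s in zip(self.pair_energies, self.strength)
            if s == "weak" and pe.pair.is_interfragment
        )

    @property
    def e_wp_intra(self) -> float:
        """Summed intrafragment weak-pair energy (diagnostic only)."""
        return sum(
            pe.energy
            for pe, s in zip(self.pair_energies, self.strength)
            if s == "weak" and not pe.pair.is_interfragment
        )

    @property
    def strong_pairs(self) -> list[PairRecord]:
        return [
            pe.pair for pe, s in zip(self.pair_energies, self.strength) if s == "strong"
        ]

    @property
    def strong_interfragment(self) -> list[PairRecord]:
        return [p for p in self.strong_pairs if p.is_interfragment]

    @property
    def e_mp2_pairs_total(self) -> float:
        return sum(pe.energy for pe in self.pair_energies)

    def to_csv(self) -> str:
        out = io.StringIO()
        out.write("spin_case,i,j,fragment_class,eps_mp2_hartree,strength\n")
        for pe, s in zip(self.pair_energies, self.strength):
            p = pe.pair
            out.write(
                f"{p.spin_case},{p.i},{p.j},{p.fragment_class},{pe.energy:.12e},{s}\n"
            )
        return out.getvalue()


def sc_mp2_pair_energies(space: CorrelationSpace) -> list[PairEnergy]:
    """Semicanonical second-order pair energies.

    Denominators use diagonal occupied Fock elements and canonical
    virtual energies; off-diagonal occupied couplings are neglected.
    With canonical (unlocalized) occupieds the pair sum plus the
    semicanonical singles equals the canonical MP2 correlation energy.
    """
    o, v = space.nocc, space.nvirt
    f = space.fock
    d_o = np.diag(f)[:o]
    d_v = np.diag(f)[o:]
    denom = d_v[:, None] + d_v[None, :]
    A_oovv = space.eri_anti[:o, :o, o:, o:]
    out = []
    for pair in space.pair_list:
        i, j = space.so_indices(pair)
        D = d_o[i] + d_o[j] - denom
        if np.min(np.abs(D)) < 1e-8:
            raise ScreeningError(
                f"vanishing MP2 denominator for pair {pair.spin_case}({pair.i},{pair.j})"
            )
        g = A_oovv[i, j]
        # 1/2 sum_ab |<ij||ab>|^2 / D  for i < j (both spin orders counted in ab)
        out.append(PairEnergy(pair=pair, energy=float(0.5 * np.sum(g * g / D))))
    return out


def sc_mp2_singles_energy(space: CorrelationSpace) -> float:
    """Semicanonical singles contribution (zero for a Brillouin reference)."""
    o = space.nocc
    f = space.fock
    d_o = np.diag(f)[:o]
    d_v = np.diag(f)[o:]
    f_ov = f[:o, o:]
    return float(np.sum(f_ov ** 2 / (d_o[:, None] - d_v[None, :])))


def classify_pairs(
    pair_energies: list[PairEnergy], t_cut_pairs: float
) -> ScreeningResult:
    """Threshold on |eps|: |eps| >= T_CutPairs is strong (inclusive).

    ``t_cut_pairs = 0`` keeps every pair strong; infinity makes every
    pair weak.  Shrinking the threshold never demotes a strong pair.
    """
    strength = [
        "strong" if abs(pe.energy) >= t_cut_pairs else "weak" for pe in pair_energies
    ]
    return ScreeningResult(
        pair_energies=list(pair_energies), strength=strength, t_cut_pairs=t_cut_pairs
    )
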