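"""Run configuration for HFLD calculations."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


@dataclass
class RunConfig:
    """All knobs of an HFLD interaction-energy calculation.

    ``reference_kind`` selects the scheme: UHF/HFLD uses UHF monomer and
    adduct energies for the mean-field interaction energy with the
    dispersion part taken from a coupled-cluster solve on the
    quasi-restricted-orbital determinant; QRO/HFLD uses the QRO
    determinant energies throughout; ROHF/HFLD uses ROHF.

    ``t_cut_pairs`` (hartree) splits occupied pairs into strong pairs
    (treated at CCSD level) and weak pairs (kept at second order) on the
    magnitude of their semicanonical MP2 pair energy.  ``0`` keeps every
    pair strong ("gold" screening).
    """

    reference_kind: str = "UHF"
    basis_name: str = "cc-pvdz"
    t_cut_pairs: float = 1e-5
    frozen_core: bool = True
    scf_conv: float = 1e-9
    cc_conv: float = 1e-8
    loc_conv: float = 1e-6
    cbs_pair: tuple[int, int] | None = None
    random_seed: int = 0
    # counterpoise monomers: charge and multiplicity per fragment label
    fragment_charges: dict = field(default_factory=lambda: {"X": 0, "Y": 0})
    fragment_multiplicities: dict = field(default_factory=lambda: {"X": 1, "Y": 1})
    population_scheme: str = "mulliken"      # or "lowdin"
    keep_all_singles: bool = True            # singles on fragments without active pairs
    scf_maxiter: int = 300
    cc_maxiter: int = 200

    def __post_init__(self):
        kind = self.reference_kind.upper()
        if kind not in ("UHF", "QRO", "ROHF"):
            raise ValueError(f"reference_kind must be UHF, QRO or ROHF, got {kind}")
        self.reference_kind = kind
        if self.t_cut_pairs < 0:
            raise ValueError("t_cut_pairs must be >= 0")
        for name in ("scf_conv", "cc_conv", "loc_conv"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.population_scheme not in ("mulliken", "lowdin"):
            raise ValueError("population_scheme must be 'mulliken' or 'lowdin'")
        if self.cbs_pair is not None:
            x, y = self.cbs_pair
            if y != x + 1:
                raise ValueError("cbs_pair must be (X, X+1)")

    def to_dict(self) -> dict:
        return asdict(self)
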