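"""Shared fixtures.  Expensive electronic-structure objects are session
scoped so the physics is computed once and inspected by many tests."""

from __future__ import annotations

import logging
import math

import numpy as np
import pytest
from hypothesis import settings

import hfld
from hfld import (
    FragmentedGeometry, build_dimer, build_qro, build_reference,
    fixture_config, solve_scf,
)
from hfld.mospace import build_correlation_space
from hfld.reference import reference_from_scf

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")

logging.getLogger("hfld").setLevel(logging.ERROR)


def make_geometry(syms, xyz, charge=0, multiplicity=1, frag=None):
    frag = frag or ("X",) * len(syms)
    return FragmentedGeometry(
        symbols=tuple(syms), coords=np.array(xyz, float), charge=charge,
        multiplicity=multiplicity, fragment_of_atom=tuple(frag),
    )


@pytest.fixture(scope="session")
def h2_geometry():
    return make_geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.7408481]],
                         frag=("X", "Y"))


@pytest.fixture(scope="session")
def h2_space(h2_geometry):
    sol = solve_scf(h2_geometry, "sto-3g", "UHF")
    ref = reference_from_scf(sol, frozen_core=False)
    return build_correlation_space(ref, localize_occupied=False,
                                   localize_virtual=False)


@pytest.fixture(scope="session")
def he_space():
    geom = make_geometry(["He"], [[0.0, 0.0, 0.0]])
    sol = solve_scf(geom, "cc-pvdz", "UHF")
    return build_correlation_space(reference_from_scf(sol, frozen_core=False),
                                   localize_occupied=False,
                                   localize_virtual=False)


@pytest.fixture(scope="session")
def he2_geometry():
    return build_dimer("he2", 3.0)


@pytest.fixture(scope="session")
def he2_uhf(he2_geometry):
    return solve_scf(he2_geometry, "cc-pvdz", "UHF")


@pytest.fixture(scope="session")
def he2_space(he2_uhf):
    """He dimer at 3 A, cc-pVDZ, localized occupieds and virtuals."""
    return build_correlation_space(reference_from_scf(he2_uhf, frozen_core=False))


@pytest.fixture(scope="session")
def ch2_geometry():
    from hfld.fixtures import A_HCH_TRIPLET, R_CH_CARBENE

    half = math.radians(A_HCH_TRIPLET / 2)
    x = R_CH_CARBENE * math.sin(half)
    z = R_CH_CARBENE * math.cos(half)
    return make_geometry(["C", "H", "H"], [[0, 0, 0], [x, 0, z], [-x, 0, z]],
                         multiplicity=3)


@pytest.fixture(scope="session")
def ch2_qro_space(ch2_geometry):
    """Triplet methylene, STO-3G, QRO reference, frozen carbon core."""
    sol = solve_scf(ch2_geometry, "sto-3g", "UHF")
    return build_correlation_space(build_qro(sol, frozen_core=True))


@pytest.fixture(scope="session")
def water_dimer_variants():
    """dE_int^HFLD of the water dimer for the three reference schemes."""
    geom = build_dimer("h2o_h2o")
    out = {}
    for kind in ("UHF", "QRO", "ROHF"):
        cfg = fixture_config("h2o_h2o", reference_kind=kind, basis_name="sto-3g")
        out[kind] = hfld.hfld_interaction_energy(geom, cfg).de_hfld_kcal
    return out


@pytest.fixture(scope="session")
def li_h2o_hfld():
    geom = build_dimer("li_h2o")
    return hfld.hfld_interaction_energy(geom, fixture_config("li_h2o"))


@pytest.fixture(scope="session")
def he2_far_hfld():
    """He dimer at 50 A: the noninteracting limit."""
    geom = build_dimer("he2", 50.0)
    return hfld.hfld_interaction_energy(geom, fixture_config("he2"))


@pytest.fixture(scope="session")
def li_h2o_nodisp():
    geom = build_dimer("li_h2o")
    return hfld.nodisp_correlation(geom, fixture_config("li_h2o"))


@pytest.fixture(scope="session")
def f_h2o_nodisp():
    geom = build_dimer("f_h2o")
    return hfld.nodisp_correlation(geom, fixture_config("f_h2o"))


@pytest.fixture(scope="session")
def li_scan_comparison():
    """HF / HFLD / full-CCSD counterpoise curves for Li...OH2."""
    cfg = fixture_config("li_h2o")
    rs = [3.0, 4.5]
    return {
        "R": rs,
        "HF": dict(hfld.scan_curve("li_h2o", "HF", rs, cfg)),
        "HFLD": dict(hfld.scan_curve("li_h2o", "HFLD", rs, cfg)),
        "CCSD": dict(hfld.scan_curve("li_h2o", "CCSD", rs, cfg)),
    }


@pytest.fixture(scope="session")
def he2_tail_curve():
    """E_disp^C-CCSD of He2 over the 8-15 A tail at aug-cc-pVDZ."""
    cfg = fixture_config("he2", basis_name="aug-cc-pvdz", t_cut_pairs=0.0)
    out = []
    for d in (8.0, 10.0, 12.0, 15.0):
        res = hfld.hfld_interaction_energy(build_dimer("he2", d), cfg)
        out.append((d, res.e_disp_ccsd))
    return out
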