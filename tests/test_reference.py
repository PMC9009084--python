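"""Reference determinants: QRO, spin contamination, Mayer bond order,
counterpoise and density deformation."""

import numpy as np
import pytest

from hfld import (
    CubeGrid, build_dimer, build_qro, build_reference, counterpoise_interaction,
    make_ghost_system, mayer_bond_order, reference_density_deformation,
    solve_scf, spin_squared,
)
from hfld.geometry import HARTREE_TO_KCAL
from hfld.reference import reference_from_scf

from conftest import make_geometry


class TestQRO:
    def test_closed_shell_qro_equals_uhf(self):
        g = make_geometry(["He"], [[0, 0, 0]])
        sol = solve_scf(g, "cc-pvdz", "UHF")
        qro = build_qro(sol)
        assert abs(qro.energy - sol.energy) < 1e-9
        assert abs(qro.s_squared) < 1e-10

    def test_one_electron_qro_uhf_rohf_coincide(self):
        g = make_geometry(["H"], [[0, 0, 0]], multiplicity=2)
        u = solve_scf(g, "cc-pvdz", "UHF")
        r = solve_scf(g, "cc-pvdz", "ROHF")
        q = build_qro(u)
        assert abs(q.energy - u.energy) < 1e-9
        assert abs(q.energy - r.energy) < 1e-9

    def test_triplet_methylene_variational_ordering(self, ch2_geometry):
        """UHF <= ROHF <= QRO, and the QRO determinant stays within a few
        millihartree of the independently converged ROHF minimum."""
        u = solve_scf(ch2_geometry, "cc-pvdz", "UHF")
        r = solve_scf(ch2_geometry, "cc-pvdz", "ROHF")
        q = build_qro(u)
        assert u.energy <= r.energy + 1e-10
        assert r.energy <= q.energy + 1e-10   # ROHF is the restricted minimum
        assert q.energy - r.energy < 5e-3
        assert abs(q.s_squared - 2.0) < 1e-10

    def test_qro_requires_majority_alpha(self):
        g = make_geometry(["He"], [[0, 0, 0]])
        sol = solve_scf(g, "cc-pvdz", "UHF")
        bad = type(sol)(**{**sol.__dict__, "n_occ": (0, 2)})
        with pytest.raises(ValueError):
            build_qro(bad)


class TestSpinSquared:
    def test_rohf_doublet_exact(self):
        g = make_geometry(["Li"], [[0, 0, 0]], multiplicity=2)
        r = solve_scf(g, "cc-pvdz", "ROHF")
        s2 = spin_squared(r.C, r.ao.overlap, r.n_occ)
        assert abs(s2 - 0.75) < 1e-10

    def test_closed_shell_zero(self):
        g = make_geometry(["He"], [[0, 0, 0]])
        s = solve_scf(g, "cc-pvdz", "UHF")
        assert abs(spin_squared(s.C, s.ao.overlap, s.n_occ)) < 1e-10

    def test_co_cation_heavily_contaminated(self):
        """2CO+ is the paper-flagged spin-contamination case: the UHF <S^2>
        deviates from the doublet value by more than 0.2."""
        g = make_geometry(["C", "O"], [[0, 0, 0], [0, 0, 1.115]], charge=1,
                          multiplicity=2)
        ref = build_reference(g, "cc-pvdz", "UHF")
        assert ref.s_squared - 0.75 > 0.2


class TestMayer:
    def test_h2_single_bond(self):
        g = make_geometry(["H", "H"], [[0, 0, 0], [0, 0, 0.7414]],
                          frag=("X", "Y"))
        r = build_reference(g, "sto-3g", "UHF")
        bo = mayer_bond_order(r.density, r.ao.overlap, r.ao.basis.ao_atom, 0, 1)
        assert abs(bo - 1.0) < 1e-8

    def test_far_helium_atoms_zero(self):
        g = make_geometry(["He", "He"], [[0, 0, 0], [0, 0, 50.0]],
                          frag=("X", "Y"))
        r = build_reference(g, "cc-pvdz", "UHF")
        bo = mayer_bond_order(r.density, r.ao.overlap, r.ao.basis.ao_atom, 0, 1)
        assert abs(bo) < 1e-8

    def test_same_atom_rejected(self):
        g = make_geometry(["He", "He"], [[0, 0, 0], [0, 0, 3.0]],
                          frag=("X", "Y"))
        r = build_reference(g, "sto-3g", "UHF")
        with pytest.raises(ValueError):
            mayer_bond_order(r.density, r.ao.overlap, r.ao.basis.ao_atom, 1, 1)


class TestCounterpoise:
    def test_noninteracting_limit(self):
        g = build_dimer("he2", 50.0)
        fn = lambda geom: solve_scf(geom, "cc-pvdz", "UHF").energy
        cp = counterpoise_interaction(g, fn, {"X": 0, "Y": 0}, {"X": 1, "Y": 1})
        assert abs(cp.delta_e_kcal) < 1e-6

    def test_relabel_symmetry(self):
        from dataclasses import replace

        g = build_dimer("he2", 3.0)
        swapped = replace(
            g,
            fragment_of_atom=tuple(
                "X" if f == "Y" else "Y" for f in g.fragment_of_atom
            ),
        )
        fn = lambda geom: solve_scf(geom, "cc-pvdz", "UHF").energy
        cp1 = counterpoise_interaction(g, fn, {"X": 0, "Y": 0}, {"X": 1, "Y": 1})
        cp2 = counterpoise_interaction(swapped, fn, {"X": 0, "Y": 0},
                                       {"X": 1, "Y": 1})
        assert abs(cp1.delta_e - cp2.delta_e) < 1e-9

    def test_ghost_basis_lowers_monomer_energy(self):
        """Variational bound: the partner's ghost basis can only lower the
        monomer energy (this IS the basis set superposition error)."""
        g = build_dimer("he2", 3.0)
        mono = make_ghost_system(g, "X")
        e_ghosted = solve_scf(mono, "cc-pvdz", "UHF").energy
        he = make_geometry(["He"], [[0, 0, 0]])
        e_isolated = solve_scf(he, "cc-pvdz", "UHF").energy
        assert e_ghosted <= e_isolated + 1e-10

    def test_cp_tail_decays_monotonically(self):
        fn = lambda geom: solve_scf(geom, "cc-pvdz", "UHF").energy
        mags = []
        for d in (4.0, 6.0, 9.0):
            cp = counterpoise_interaction(
                build_dimer("he2", d), fn, {"X": 0, "Y": 0}, {"X": 1, "Y": 1}
            )
            mags.append(abs(cp.delta_e))
        assert mags[0] > mags[1] > mags[2]


class TestDensityDeformation:
    def _refs(self, d):
        g = build_dimer("he2", d)
        ad = build_reference(g, "cc-pvdz", "UHF")
        mx = build_reference(make_ghost_system(g, "X"), "cc-pvdz", "UHF")
        my = build_reference(make_ghost_system(g, "Y"), "cc-pvdz", "UHF")
        return g, ad, mx, my

    def test_noninteracting_limit_vanishes(self):
        g, ad, mx, my = self._refs(50.0)
        grid = CubeGrid(origin=[-3, -3, -3], axes=np.eye(3) * 1.0,
                        shape=(7, 7, 10))
        rho = reference_density_deformation(ad, mx, my, grid)
        assert np.max(np.abs(rho)) < 1e-8

    def test_grid_integral_conserves_electrons(self):
        g, ad, mx, my = self._refs(3.0)
        grid = CubeGrid.around(g, margin=6.0, spacing=0.35)
        rho = reference_density_deformation(ad, mx, my, grid)
        total = rho.sum() * grid.voxel_volume
        assert abs(total) < 1e-3

    def test_electron_count_mismatch_rejected(self):
        g, ad, mx, my = self._refs(3.0)
        cation = build_reference(
            make_ghost_system(g, "X", real_charge=1, real_multiplicity=2),
            "cc-pvdz", "UHF",
        )
        grid = CubeGrid(origin=[0, 0, 0], axes=np.eye(3), shape=(2, 2, 2))
        with pytest.raises(ValueError, match="electron counts"):
            reference_density_deformation(ad, cation, my, grid)
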