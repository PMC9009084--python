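"""Geometry, fragment-spec and cube I/O behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hfld import (
    CubeGrid, FragmentedGeometry, make_ghost_system, parse_fragment_spec,
    read_cube, read_xyz_with_fragments, write_cube, write_xyz,
)
from hfld.geometry import GeometryError

from conftest import make_geometry


WATER_XYZ = """3
water
O   0.000000   0.000000   0.000000
H   0.757000   0.000000   0.586000
H  -0.757000   0.000000   0.586000
"""


def test_read_single_fragment_water_is_monomer(tmp_path):
    p = tmp_path / "w.xyz"
    p.write_text(WATER_XYZ)
    g = read_xyz_with_fragments(p, "1-3:X")
    assert g.is_monomer
    assert g.symbols == ("O", "H", "H")
    assert g.n_electrons == 10


def test_fragment_spec_out_of_range_raises(tmp_path):
    p = tmp_path / "w.xyz"
    p.write_text(WATER_XYZ)
    with pytest.raises(GeometryError):
        read_xyz_with_fragments(p, "1:X,2-4:Y")


def test_fragment_spec_unassigned_atom_raises():
    with pytest.raises(GeometryError, match="unassigned"):
        parse_fragment_spec("1:X,3:Y", 3)


def test_malformed_xyz_raises(tmp_path):
    p = tmp_path / "bad.xyz"
    p.write_text("not an xyz\n")
    with pytest.raises(GeometryError):
        read_xyz_with_fragments(p, "1:X")


def test_li_water_adduct_doublet(tmp_path):
    p = tmp_path / "li.xyz"
    p.write_text(
        "4\nLi...OH2\nLi 0 0 -1.9\nO 0 0 0\nH 0.76 0 0.59\nH -0.76 0 0.59\n"
    )
    g = read_xyz_with_fragments(p, "1:X,2-4:Y", charge=0, multiplicity=2)
    assert not g.is_monomer
    assert g.atoms_of("X") == [0]
    assert (g.n_alpha, g.n_beta) == (7, 6)


def test_multiplicity_parity_validated():
    with pytest.raises(GeometryError, match="multiplicity"):
        make_geometry(["He"], [[0, 0, 0]], multiplicity=2)


@given(
    n=st.integers(2, 12),
    cut=st.integers(1, 11),
)
def test_fragment_spec_round_trip(n, cut):
    """Contiguous two-fragment specs parse to the labels they encode."""
    cut = min(cut, n - 1)
    spec = f"1-{cut}:X,{cut + 1}-{n}:Y"
    labels = parse_fragment_spec(spec, n)
    assert labels == ("X",) * cut + ("Y",) * (n - cut)


def test_xyz_round_trip_preserves_coordinates(tmp_path):
    g = make_geometry(
        ["O", "H"], [[0.123456789, -1.0, 2.5], [0.0, 0.99999999, -3.25]],
        charge=-1, frag=("X", "Y"),
    )
    p = tmp_path / "g.xyz"
    write_xyz(g, p)
    g2 = read_xyz_with_fragments(p, "1:X,2:Y", charge=-1)
    assert np.allclose(g2.coords, g.coords, atol=1e-8)
    assert g2.fragment_of_atom == g.fragment_of_atom


class TestGhostSystems:
    def test_he_dimer_ghost_counts(self):
        g = make_geometry(["He", "He"], [[0, 0, 0], [0, 0, 3]], frag=("X", "Y"))
        gx = make_ghost_system(g, "X")
        assert gx.n_electrons == 2
        assert gx.atomic_numbers.tolist() == [2, 0]
        assert gx.is_monomer

    def test_ghosting_partitions_atoms(self):
        g = make_geometry(
            ["Li", "O", "H", "H"],
            [[0, 0, -1.9], [0, 0, 0], [0.76, 0, 0.59], [-0.76, 0, 0.59]],
            multiplicity=2, frag=("X", "Y", "Y", "Y"),
        )
        gx = make_ghost_system(g, "X", 0, 2)
        gy = make_ghost_system(g, "Y", 0, 1)
        ghosts_x = np.array(gx.is_ghost)
        ghosts_y = np.array(gy.is_ghost)
        assert np.array_equal(ghosts_x, ~ghosts_y)
        assert gx.n_electrons + gy.n_electrons == g.n_electrons

    def test_charged_fragment_split(self):
        g = make_geometry(
            ["C", "O", "O", "H", "H"],
            [[0, 0, -2.3], [0, 0, -3.4], [0, 0, 0], [0.76, 0, 0.59],
             [-0.76, 0, 0.59]],
            charge=1, multiplicity=2, frag=("X", "X", "Y", "Y", "Y"),
        )
        gx = make_ghost_system(g, "X", 1, 2)
        assert gx.charge == 1 and gx.multiplicity == 2
        assert gx.n_electrons == 13

    def test_monomer_cannot_be_ghosted(self):
        g = make_geometry(["He"], [[0, 0, 0]])
        with pytest.raises(GeometryError):
            make_ghost_system(g, "X")


class TestCube:
    def test_constant_zero_round_trip(self, tmp_path):
        g = make_geometry(["He", "He"], [[0, 0, 0], [0, 0, 3]], frag=("X", "Y"))
        grid = CubeGrid(origin=[-1, -1, -1], axes=np.eye(3) * 0.5, shape=(2, 2, 2))
        vals = np.zeros((2, 2, 2))
        p = tmp_path / "z.cube"
        write_cube(vals, g, grid, p)
        back, grid2, charges = read_cube(p)
        assert np.allclose(back, 0.0)
        assert charges.tolist() == [2.0, 2.0]

    def test_nontrivial_field_round_trip(self, tmp_path):
        g = make_geometry(["H"], [[0, 0, 0]], multiplicity=2)
        grid = CubeGrid(origin=[-2, -2, -2], axes=np.eye(3) * 0.8, shape=(5, 4, 3))
        rng = np.random.default_rng(7)
        vals = rng.normal(size=grid.shape)
        p = tmp_path / "f.cube"
        write_cube(vals, g, grid, p)
        back, grid2, _ = read_cube(p)
        assert np.allclose(back, vals, rtol=1e-4, atol=1e-8)
        assert np.allclose(grid2.axes, grid.axes)

    def test_nonorthogonal_axes_rejected(self):
        axes = np.array([[1.0, 0.1, 0.0], [0.0, 1.0, 0.0], [0.0, 0.0, 1.0]])
        with pytest.raises(GeometryError, match="orthogonal"):
            CubeGrid(origin=[0, 0, 0], axes=axes, shape=(2, 2, 2))

    def test_shape_mismatch_rejected(self, tmp_path):
        g = make_geometry(["H"], [[0, 0, 0]], multiplicity=2)
        grid = CubeGrid(origin=[0, 0, 0], axes=np.eye(3), shape=(2, 2, 2))
        with pytest.raises(GeometryError):
            write_cube(np.zeros((3, 2, 2)), g, grid, tmp_path / "x.cube")
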