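"""End-to-end HFLD pipeline behaviour and the DID map."""

from dataclasses import replace

import numpy as np
import pytest

import hfld
from hfld import (
    CubeGrid, build_dimer, did_grid, fixture_config, hfld_interaction_energy,
    read_cube, write_cube,
)
from hfld.geometry import HARTREE_TO_KCAL
from hfld.led import run_correlation_stage


def test_eq6_additivity_is_exact(li_h2o_hfld):
    r = li_h2o_hfld
    assert r.de_hfld == r.de_ref + r.e_disp_ccsd
    assert abs(r.de_hfld_kcal - (r.de_ref_kcal + r.e_disp_kcal)) < 1e-9


def test_li_water_binding_is_attractive_and_disp_negative(li_h2o_hfld):
    """Metal-water adduct: bound at the mean-field level already, with a
    negative CCSD-level dispersion on top."""
    r = li_h2o_hfld
    assert r.de_ref_kcal < -5.0
    assert r.e_disp_ccsd < 0.0
    assert r.de_hfld < r.de_ref


def test_fragment_relabel_symmetry():
    """Swapping the X/Y labels leaves every Eq-6 component unchanged."""
    g = build_dimer("he2", 3.0)
    cfg = fixture_config("he2")
    r1 = hfld_interaction_energy(g, cfg)
    swapped = replace(
        g,
        fragment_of_atom=tuple("X" if f == "Y" else "Y"
                               for f in g.fragment_of_atom),
    )
    r2 = hfld_interaction_energy(swapped, cfg)
    assert abs(r1.e_disp_ccsd - r2.e_disp_ccsd) < 1e-10
    assert abs(r1.de_hfld - r2.de_hfld) < 1e-8


def test_monomer_input_rejected():
    from conftest import make_geometry
    from hfld.led import LEDError

    g = make_geometry(["He"], [[0, 0, 0]])
    with pytest.raises(LEDError):
        hfld_interaction_energy(g, fixture_config("he2"))


def test_screening_threshold_moves_pairs_to_weak():
    """A huge T_CutPairs turns HFLD into the pure MP2-level dispersion
    estimate; the default keeps CC pairs.  Both must give negative
    dispersion for He2 near equilibrium."""
    g = build_dimer("he2", 3.0)
    res_cc = hfld_interaction_energy(g, fixture_config("he2", t_cut_pairs=0.0))
    res_wp = hfld_interaction_energy(g, fixture_config("he2", t_cut_pairs=1.0))
    assert len(res_wp.stage.screening.strong_pairs) == 0
    assert res_wp.e_disp_ccsd < 0
    assert res_cc.e_disp_ccsd < 0
    # MP2-level and CC-level dispersion agree on the order of magnitude
    assert 0.2 < res_wp.e_disp_ccsd / res_cc.e_disp_ccsd < 5.0


@pytest.fixture(scope="module")
def ch4_water_stage():
    cfg = fixture_config("ch4_3h2o", basis_name="sto-3g", t_cut_pairs=0.0)
    g = build_dimer("ch4_3h2o")
    return g, run_correlation_stage(g, cfg, active="strong-inter")


class TestDID:

    def test_grid_integral_matches_mapped_energy(self, ch4_water_stage):
        g, stage = ch4_water_stage
        grid = CubeGrid.around(g, margin=5.0, spacing=0.45)
        vals = did_grid(stage, grid, units_kcal=False)
        mapped = stage.led.e_disp_ccsd
        integral = vals.sum() * grid.voxel_volume
        assert mapped < 0
        assert abs(integral - mapped) < 0.01 * abs(mapped)

    def test_field_localizes_on_solvation_contact(self, ch4_water_stage):
        """The dispersion density lives on the solute/first-shell contact
        (pair orbital densities) and vanishes away from the cluster."""
        g, stage = ch4_water_stage
        grid = CubeGrid.around(g, margin=4.0, spacing=0.4)
        vals = np.abs(did_grid(stage, grid))
        peak_val = vals.max()
        peak = np.unravel_index(np.argmax(vals), vals.shape)
        r_peak = grid.origin + np.array(peak, float) @ grid.axes
        atoms = g.coords_bohr
        # peak sits on the cluster (within ~1.3 A of some atom), and the
        # contributing orbitals put it no farther from the solute carbon
        # than the far side of the first shell
        assert np.min(np.linalg.norm(atoms - r_peak, axis=1)) < 2.5
        d_c = np.linalg.norm(r_peak - atoms[0])
        r_shell = max(np.linalg.norm(atoms[k] - atoms[0]) for k in range(5, len(atoms)))
        assert d_c <= r_shell + 1e-9
        # far from the cluster the field is negligible
        corner = vals[0, 0, 0]
        assert corner < 1e-3 * peak_val

    def test_zero_dispersion_gives_zero_field(self, ch4_water_stage):
        g, stage = ch4_water_stage
        import copy

        st2 = copy.copy(stage)
        led = copy.deepcopy(stage.led)
        for p in led.pairs:
            p.eps_disp = 0.0
        led.e_wp_inter = 0.0
        st2.led = led
        scr = copy.deepcopy(stage.screening)
        st2.screening = scr
        grid = CubeGrid.around(g, margin=3.0, spacing=0.8)
        vals = did_grid(st2, grid, include_weak=False)
        assert np.allclose(vals, 0.0)

    def test_cube_round_trip(self, ch4_water_stage, tmp_path):
        g, stage = ch4_water_stage
        grid = CubeGrid.around(g, margin=3.0, spacing=0.8)
        vals = did_grid(stage, grid)
        p = tmp_path / "did.cube"
        write_cube(vals, g, grid, p)
        back, grid2, charges = read_cube(p)
        assert back.shape == vals.shape
        assert np.allclose(back, vals, rtol=1e-4, atol=1e-10)
        assert int(charges.sum()) == sum(z for z in g.atomic_numbers)
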