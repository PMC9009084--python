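"""LED dispersion partition, HFLD assembly, extrapolations, DID."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hfld import (
    ExtrapolationSettings, assemble_ld_energy, cbs_extrapolate,
    cps_extrapolate, decompose_pair_dispersion, solve_pair_restricted_uccsd,
)
from hfld.led import LEDError
from hfld.screening import classify_pairs, sc_mp2_pair_energies


@pytest.fixture(scope="module")
def he2_led(he2_space):
    inter = [p for p in he2_space.pair_list if p.is_interfragment]
    cc = solve_pair_restricted_uccsd(he2_space, inter, cc_conv=1e-12)
    led_pairs = decompose_pair_dispersion(he2_space, cc, inter)
    return he2_space, cc, led_pairs


class TestDecomposition:
    def test_conservation_per_pair(self, he2_led):
        _, _, led_pairs = he2_led
        for p in led_pairs:
            assert abs(p.eps - p.eps_disp - p.eps_nodisp) < 1e-15

    def test_pair_energies_match_cc_solver(self, he2_led):
        """The localized-virtual-basis pair energies must equal the
        canonical-basis ones (unitary invariance of each pair sum)."""
        sp, cc, led_pairs = he2_led
        for p in led_pairs:
            i, j = sp.so_indices(p.pair)
            assert abs(p.eps - cc.pair_energies[(i, j)]) < 1e-11

    def test_all_virtuals_one_fragment_means_no_dispersion(self, he2_led):
        """If every virtual sat on fragment X there would be no
        opposite-fragment virtual pairs at all."""
        import copy

        sp, cc, _ = he2_led
        sp2 = copy.copy(sp)
        va = copy.deepcopy(sp.virt_assignment)
        for asg in va:
            asg.labels[:] = ["X"] * len(asg.labels)
        sp2.virt_assignment = (va[0], va[1])
        inter = [p for p in sp2.pair_list if p.is_interfragment]
        led = decompose_pair_dispersion(sp2, cc, inter)
        for p in led:
            assert p.eps_disp == 0.0
            assert abs(p.eps_nodisp - p.eps) < 1e-15

    def test_long_range_interfragment_pairs_are_pure_dispersion(self):
        """At 5 A the He2 interfragment correlation is essentially all
        dispersion (opposite-fragment virtual pairs)."""
        from hfld import build_dimer, solve_scf
        from hfld.mospace import build_correlation_space
        from hfld.reference import reference_from_scf

        g = build_dimer("he2", 5.0)
        sp = build_correlation_space(
            reference_from_scf(solve_scf(g, "cc-pvdz", "UHF"), frozen_core=False)
        )
        inter = [p for p in sp.pair_list if p.is_interfragment]
        cc = solve_pair_restricted_uccsd(sp, inter, cc_conv=1e-13)
        led = decompose_pair_dispersion(sp, cc, inter)
        ab = [p for p in led if p.pair.spin_case == "ab"]
        for p in ab:
            assert p.eps < 0
            assert p.eps_disp / p.eps > 0.95

    def test_brute_force_term_classification(self, he2_led):
        """Explicit loop over every (a, b) term reproduces the vectorized
        genuine+exchange split."""
        sp, cc, led_pairs = he2_led
        o = sp.nocc
        U = sp.virt_unitary_so
        oovv = np.einsum("ijab,ac,bd->ijcd", sp.eri_anti[:o, :o, o:, o:], U, U)
        tau = np.einsum("ijab,ac,bd->ijcd", cc.amplitudes.tau(), U, U)
        frag = sp.virt_frag
        for p in led_pairs:
            i, j = sp.so_indices(p.pair)
            disp = 0.0
            for a in range(sp.nvirt):
                for b in range(sp.nvirt):
                    if frag[a] != frag[b]:
                        disp += 0.5 * oovv[i, j, a, b] * tau[i, j, a, b]
            assert abs(disp - p.eps_disp) < 1e-12

    def test_intrafragment_pair_rejected(self, he2_led):
        sp, cc, _ = he2_led
        intra = [p for p in sp.pair_list if not p.is_interfragment]
        with pytest.raises(LEDError):
            decompose_pair_dispersion(sp, cc, [intra[0]])


class TestAssembly:
    def test_all_strong_sums_dispersion(self, he2_led):
        sp, cc, led_pairs = he2_led
        scr = classify_pairs(sc_mp2_pair_energies(sp), 0.0)
        led = assemble_ld_energy(led_pairs, scr)
        assert led.e_wp_inter == 0.0
        assert abs(led.e_disp_ccsd - sum(p.eps_disp for p in led_pairs)) < 1e-15

    def test_all_weak_reduces_to_mp2_estimate(self, he2_space):
        scr = classify_pairs(sc_mp2_pair_energies(he2_space), np.inf)
        led = assemble_ld_energy([], scr)
        assert abs(led.e_disp_ccsd - scr.e_wp_inter) < 1e-18
        assert led.e_disp_ccsd < 0

    def test_mismatched_pair_lists_rejected(self, he2_led):
        sp, cc, led_pairs = he2_led
        scr = classify_pairs(sc_mp2_pair_energies(sp), np.inf)
        with pytest.raises(LEDError):
            assemble_ld_energy(led_pairs, scr)


class TestExtrapolation:
    def test_fixed_point(self):
        out = cbs_extrapolate(-1.0, -1.0, -0.2, -0.2)
        assert abs(out["reference_cbs"] - (-1.0)) < 1e-12
        assert abs(out["correlation_cbs"] - (-0.2)) < 1e-12

    def test_correlation_closed_form_34(self):
        e3, e4 = -0.250, -0.260
        out = cbs_extrapolate(-1.0, -1.0, e3, e4,
                              ExtrapolationSettings(cardinals=(3, 4)))
        assert abs(out["correlation_cbs"] - (64 * e4 - 27 * e3) / 37) < 1e-12

    def test_monotone_series_overshoots(self):
        e3, e4 = -0.250, -0.260   # E3 > E4 (less negative), both < 0
        out = cbs_extrapolate(0.0, 0.0, e3, e4)
        assert out["correlation_cbs"] < e4

    def test_invalid_cardinals_rejected(self):
        with pytest.raises(ValueError):
            cbs_extrapolate(0, 0, 0, 0, ExtrapolationSettings(cardinals=(3, 3)))

    def test_cps_endpoints(self):
        s0 = ExtrapolationSettings(cps_factor=0.0)
        s1 = ExtrapolationSettings(cps_factor=1.0)
        assert cps_extrapolate(-1.0, -2.0, s0) == -1.0
        assert cps_extrapolate(-1.0, -2.0, s1) == -2.0
        assert cps_extrapolate(-1.5, -1.5) == -1.5

    @given(
        ex=st.floats(-2, 0), ey=st.floats(-2, 0), f=st.floats(0, 3),
    )
    def test_cps_affine_in_f(self, ex, ey, f):
        val = cps_extrapolate(ex, ey, ExtrapolationSettings(cps_factor=f))
        assert abs(val - (ex + f * (ey - ex))) < 1e-12
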