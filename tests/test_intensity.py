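"""Wilson/anisotropy fits, normalization, moments, anomaly scans, screws, R factors."""

import gemmi
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from refltriage import UnitCell, parse_spacegroup
from refltriage.formfactors import f0, known_elements
from refltriage.intensity import (aniso_fit, detect_screw_axes, ice_ring_scan,
                                  moments, normalize, nz_curves, r_factors,
                                  wilson_fit)
from refltriage.reflections import bin_by_resolution
from refltriage.simulate import SyntheticConfig, enumerate_unique_hkl, simulate_dataset

from conftest import make_merged_set


def composition_of(ds):
    comp = {}
    for a in ds.expanded_atoms:
        comp[a.element] = comp.get(a.element, 0) + 1
    return comp


class TestFormFactors:
    def test_matches_gemmi_it92_table(self):
        s2 = np.linspace(0.0, 0.25, 20)
        # gemmi ships alternative H coefficients, so H is only checked at rest
        for el in set(known_elements()) - {"H"}:
            ours = f0(el, s2)
            theirs = np.array([gemmi.Element(el).it92.calculate_sf(x) for x in s2])
            np.testing.assert_allclose(ours, theirs, rtol=1e-4)
        assert f0("H", np.array([0.0]))[0] == pytest.approx(1.0, abs=0.01)

    def test_unknown_element_falls_back_to_electron_count(self):
        np.testing.assert_allclose(f0("Se", np.array([0.0, 0.1]), fallback_z=34), 34.0)
        with pytest.raises(KeyError):
            f0("Se", np.array([0.0]))


class TestWilson:
    @pytest.mark.parametrize("b_true", [10.0, 30.0, 60.0])
    def test_recovers_b(self, b_true):
        cfg = SyntheticConfig(seed=31, cell=(30, 34, 40, 90, 100, 90),
                              sg_symbol="P21", n_atoms=80, d_min=2.0,
                              b_range=(b_true, b_true), noise_k=0.0)
        ds = simulate_dataset(cfg)
        wf = wilson_fit(ds.reflections, composition_of(ds))
        assert wf.B_iso == pytest.approx(b_true, rel=0.10)

    def test_b_zero(self):
        cfg = SyntheticConfig(seed=32, cell=(30, 34, 40, 90, 100, 90),
                              sg_symbol="P21", n_atoms=80, d_min=2.0,
                              b_range=(0.0, 0.0), noise_k=0.0)
        ds = simulate_dataset(cfg)
        wf = wilson_fit(ds.reflections, composition_of(ds))
        assert abs(wf.B_iso) < 1.0

    def test_scale_linearity(self, clean_p21):
        rs = clean_p21.reflections
        comp = composition_of(clean_p21)
        wf1 = wilson_fit(rs, comp)
        scaled = rs.with_data(rs.data.assign(I=rs.data["I"] * 10.0))
        wf2 = wilson_fit(scaled, comp)
        assert wf2.K == pytest.approx(10.0 * wf1.K, rel=1e-9)
        assert wf2.B_iso == pytest.approx(wf1.B_iso, abs=1e-9)

    def test_low_resolution_rejected(self):
        cell = UnitCell(30, 34, 40)
        sg = parse_spacegroup("P1")
        hkl = enumerate_unique_hkl(cell, sg, 5.0)
        rs = make_merged_set(hkl, np.ones(len(hkl)), cell, sg)
        with pytest.raises(ValueError, match="resolution too low"):
            wilson_fit(rs, {"C": 50})


class TestNormalize:
    def test_shell_mean_e2_is_one_exactly(self, clean_p21):
        norm = normalize(clean_p21.reflections)
        df = norm.data[~norm.data["absent"]]
        for _, grp in df.groupby("shell"):
            assert grp["E2"].mean() == pytest.approx(1.0, abs=1e-10)

    def test_constant_intensities_give_unit_e2(self):
        cell = UnitCell(20, 24, 28)
        sg = parse_spacegroup("P1")
        hkl = enumerate_unique_hkl(cell, sg, 3.0)
        rs = make_merged_set(hkl, np.full(len(hkl), 7.0), cell, sg)
        norm = normalize(rs)
        np.testing.assert_allclose(norm.data["E2"], 1.0, atol=1e-12)

    def test_epsilon_corrected_relative_to_naive_z(self):
        """An ε=2 axial reflection in an ε=1 shell gets E² = Z/2."""
        cell = UnitCell(20, 24, 28, 90, 100, 90)
        sg = parse_spacegroup("P2")
        hkl = enumerate_unique_hkl(cell, sg, 3.0)
        rs = make_merged_set(hkl, np.full(len(hkl), 10.0), cell, sg)
        norm = normalize(rs, bin_by_resolution(rs, n_shells=1))
        df = norm.data
        axial = (df["epsilon"] == 2)
        assert axial.any()
        ratio = (df.loc[axial, "E2"] / df.loc[axial, "Z"]).to_numpy()
        # halved up to the (small) effect of epsilon on the shell mean
        np.testing.assert_allclose(ratio, 0.5, rtol=0.01)


class TestMomentsAndNZ:
    def test_untwinned_acentric_moments(self, p1_big):
        mom = moments(normalize(p1_big.reflections))
        assert mom.I2_over_I_sq_acentric == pytest.approx(
            mom.expected_untwinned["I2_over_I_sq"], abs=0.05)
        assert mom.mean_abs_E2m1 == pytest.approx(
            mom.expected_untwinned["mean_abs_E2m1"], abs=0.02)

    def test_equal_intensities_ratio_is_one(self):
        cell = UnitCell(20, 24, 28)
        sg = parse_spacegroup("P1")
        hkl = enumerate_unique_hkl(cell, sg, 3.0)
        rs = make_merged_set(hkl, np.full(len(hkl), 3.0), cell, sg)
        mom = moments(normalize(rs))
        assert mom.I2_over_I_sq_acentric == pytest.approx(1.0, abs=1e-12)

    def test_nz_acentric_closed_form(self, p1_big):
        norm = normalize(p1_big.reflections)
        nz = nz_curves(norm)
        np.testing.assert_allclose(nz.acentric_ref, 1.0 - np.exp(-nz.z_grid),
                                   atol=1e-12)
        assert np.max(np.abs(nz.acentric - nz.acentric_ref)) < 0.02
        n_at_1 = (norm.acentric()["Z"] <= 1.0).mean()
        assert n_at_1 == pytest.approx(1 - np.exp(-1), abs=0.02)

    def test_nz_zero_for_positive_data(self, p1_big):
        norm = normalize(p1_big.reflections)
        ac = norm.acentric()["Z"].to_numpy()
        assert (ac <= 0).mean() == 0.0


class TestIceRings:
    def test_smooth_data_clean(self, clean_p21):
        scan = ice_ring_scan(clean_p21.reflections)
        assert scan.performed
        assert not scan.ice_rings and not scan.other_anomalies

    def test_injected_ring_flagged(self, clean_p21):
        rs = clean_p21.reflections
        rs2 = rs.with_data(rs.data.copy())
        band = (rs2.d > 3.655) & (rs2.d < 3.685)
        rs2.data.loc[band, "I"] *= 5.0
        scan = ice_ring_scan(rs2)
        assert len(scan.ice_rings) == 1
        assert scan.ice_rings[0]["d_ice"] == pytest.approx(3.67)
        assert not scan.other_anomalies

    def test_non_ice_spike_reported_separately(self, clean_p21):
        rs = clean_p21.reflections
        rs2 = rs.with_data(rs.data.copy())
        band = (rs2.d > 3.085) & (rs2.d < 3.115)
        rs2.data.loc[band, "I"] *= 5.0
        scan = ice_ring_scan(rs2)
        assert not scan.ice_rings
        assert len(scan.other_anomalies) == 1

    def test_low_resolution_skipped(self):
        cell = UnitCell(30, 34, 40)
        sg = parse_spacegroup("P1")
        hkl = enumerate_unique_hkl(cell, sg, 4.5)
        rs = make_merged_set(hkl, np.ones(len(hkl)), cell, sg)
        assert not ice_ring_scan(rs).performed


class TestAniso:
    def test_recovers_diagonal_tensor(self):
        cfg = SyntheticConfig(seed=33, cell=(30, 36, 44, 90, 90, 90),
                              sg_symbol="P1", n_atoms=100, d_min=2.0,
                              b_range=(0, 0), b_tensor=(10, 10, 40, 0, 0, 0),
                              noise_k=0.0)
        ds = simulate_dataset(cfg)
        af = aniso_fit(ds.reflections, composition_of(ds))
        np.testing.assert_allclose(np.sort(af.eigenvalues), [10, 10, 40], rtol=0.15)

    def test_isotropic_data_near_zero_delta(self):
        cfg = SyntheticConfig(seed=36, cell=(30, 36, 44, 90, 90, 90),
                              sg_symbol="P1", n_atoms=100, d_min=2.0,
                              b_range=(20, 20), noise_k=0.0)
        ds = simulate_dataset(cfg)
        af = aniso_fit(ds.reflections, composition_of(ds))
        assert af.delta_B < 2.0

    def test_cubic_constrained_isotropic(self):
        cfg = SyntheticConfig(seed=34, cell=(40, 40, 40, 90, 90, 90),
                              sg_symbol="P213", n_atoms=40, d_min=2.0, noise_k=0.0)
        ds = simulate_dataset(cfg)
        af = aniso_fit(ds.reflections, composition_of(ds))
        assert af.delta_B == 0.0 and af.constrained_isotropic

    def test_isotropic_constraint_reduces_to_wilson(self, clean_p21):
        comp = composition_of(clean_p21)
        af = aniso_fit(clean_p21.reflections, comp, constrain="isotropic")
        wf = wilson_fit(clean_p21.reflections, comp)
        assert af.eigenvalues[0] == pytest.approx(wf.B_iso, abs=1e-12)


class TestScrews:
    @pytest.mark.parametrize("sym,cell,expected", [
        ("P21", (30, 34, 40, 90, 100, 90), {("b", "21")}),
        ("P2", (30, 34, 40, 90, 100, 90), set()),
        ("P41", (34, 34, 44, 90, 90, 90), {("c", "41/43")}),
        ("P4", (34, 34, 44, 90, 90, 90), set()),
    ])
    def test_simulated_screws_detected(self, sym, cell, expected):
        cfg = SyntheticConfig(seed=35, cell=cell, sg_symbol=sym, n_atoms=80,
                              d_min=2.2, noise_k=0.03)
        ds = simulate_dataset(cfg)
        res = detect_screw_axes(ds.reflections)
        found = {(r["axis"], r["screw"]) for r in res
                 if r.get("verdict") == "screw present"}
        assert found == expected

    def test_no_axial_reflections_indeterminate(self, clean_p21):
        rs = clean_p21.reflections
        hkl = rs.hkl
        axial = ((hkl != 0).sum(axis=1) == 1)
        stripped = rs.with_data(rs.data[~axial])
        res = detect_screw_axes(stripped)
        assert all(r["verdict"] == "indeterminate" for r in res)


class TestRFactors:
    def test_identical_amplitudes(self):
        res = r_factors([3.0, 4.0, 5.0], [3.0, 4.0, 5.0], [False, False, True])
        assert res.r_work == 0.0 and res.r_free == 0.0

    @given(c=st.floats(0.01, 100.0))
    def test_uniform_scale_absorbed(self, c):
        fo = np.array([10.0, 20.0, 30.0, 5.0])
        res = r_factors(fo, c * fo)
        assert res.scale == pytest.approx(1.0 / c, rel=1e-9)
        assert res.r_work == pytest.approx(0.0, abs=1e-12)

    def test_three_term_hand_example(self):
        """F_obs=(10,20,30) vs F_model=(10,20,60): k = 2300/4100 = 23/41,
        R = (180+360+150)/41/60 = 23/82."""
        res = r_factors([10.0, 20.0, 30.0], [10.0, 20.0, 60.0])
        assert res.scale == pytest.approx(23 / 41, rel=1e-12)
        assert res.r_work == pytest.approx(23 / 82, rel=1e-12)

    def test_empty_free_set_reported_undefined(self):
        res = r_factors([1.0, 2.0], [1.0, 2.0])
        assert res.r_free is None
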