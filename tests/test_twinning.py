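"""Twin-law enumeration, L/H/Britton statistics, detwinning, correlation."""

import numpy as np
import pytest

from refltriage import UnitCell, parse_spacegroup
from refltriage.intensity import moments, normalize
from refltriage.simulate import (SyntheticConfig, apply_twin, enumerate_unique_hkl,
                                 simulate_dataset)
from refltriage.twinning import (britton, candidate_twin_laws, detwin, h_test,
                                 l_reference_moments, l_test, twin_correlation)

from conftest import make_merged_set


def twinned_set(ds, law, alpha, sigI=None):
    """Apply twinning at intensity level to a noise-free dataset."""
    rs = ds.reflections
    I_true = ds.true_intensity
    I_tw, kept = apply_twin(I_true, rs.hkl, law, alpha, rs.sg)
    return make_merged_set(rs.hkl[kept], I_tw[kept], rs.cell, rs.sg, sigI=sigI)


class TestCandidateLaws:
    def test_orthorhombic_holohedry_has_no_laws(self):
        laws = candidate_twin_laws(UnitCell(30, 34, 40), parse_spacegroup("P212121"))
        assert laws == []

    def test_p41_single_twofold(self):
        laws = candidate_twin_laws(UnitCell(42, 42, 56), parse_spacegroup("P41"))
        assert len(laws) == 1
        law = laws[0]
        assert law.kind == "merohedral"
        sg_rots = parse_spacegroup("P41").rotation_stack()
        sq = law.operator @ law.operator
        assert any(np.array_equal(sq, r) for r in sg_rots)
        assert not any(np.array_equal(law.operator, r) for r in sg_rots)

    def test_trigonal_has_three_laws(self):
        laws = candidate_twin_laws(UnitCell(40, 40, 50, 90, 90, 120),
                                   parse_spacegroup("P31"))
        assert len(laws) == 3

    def test_monoclinic_metric_trigger(self):
        sg = parse_spacegroup("P2")
        assert candidate_twin_laws(UnitCell(30, 34, 40, 90, 104, 90), sg) == []
        laws = candidate_twin_laws(UnitCell(30, 34, 40, 90, 90.2, 90), sg)
        assert laws and all(lw.kind == "pseudo-merohedral" for lw in laws)
        assert all(lw.metric_deviation > 0 for lw in laws)

    def test_operators_preserve_the_lattice_metric(self):
        cell = UnitCell(42, 42, 56)
        gstar = cell.reciprocal_metric_tensor()
        for lw in candidate_twin_laws(cell, parse_spacegroup("P4")):
            np.testing.assert_allclose(lw.operator @ gstar @ lw.operator.T,
                                       gstar, atol=1e-12)


class TestLTest:
    def test_untwinned_matches_mc_oracle(self, p1_big):
        res = l_test(normalize(p1_big.reflections), seed=1)
        ref = l_reference_moments(twinned=False)
        assert res.mean_abs_L == pytest.approx(ref["mean_abs_L"], abs=0.01)
        assert res.mean_L2 == pytest.approx(ref["mean_L2"], abs=0.01)

    def test_perfect_twin_matches_mc_oracle(self, p1_big, p1_big_twin_law):
        rs = twinned_set(p1_big, p1_big_twin_law, 0.5)
        res = l_test(normalize(rs), seed=1)
        ref = l_reference_moments(twinned=True)
        assert res.mean_abs_L == pytest.approx(ref["mean_abs_L"], abs=0.01)
        assert res.mean_L2 == pytest.approx(ref["mean_L2"], abs=0.01)

    def test_identical_intensities_give_zero_l(self):
        cell = UnitCell(24, 26, 28)
        sg = parse_spacegroup("P1")
        hkl = enumerate_unique_hkl(cell, sg, 2.2)
        rs = make_merged_set(hkl, np.full(len(hkl), 5.0), cell, sg)
        res = l_test(normalize(rs), seed=0)
        assert res.mean_abs_L == 0.0 and res.mean_L2 == 0.0

    def test_small_set_rejected(self, clean_p21):
        rs = clean_p21.reflections
        small = rs.with_data(rs.data.iloc[:1500])
        with pytest.raises(ValueError, match="insufficient pairs"):
            l_test(normalize(small), seed=0)

    def test_robust_to_tncs_modulation(self):
        """The all-even offset pairing keeps ⟨|L|⟩ at the untwinned value in
        the presence of tNCS, while naive unit-offset pairing is biased —
        the rationale for the pairing rule."""
        cfg = SyntheticConfig(seed=61, cell=(36, 40, 44, 90, 90, 90),
                              sg_symbol="P1", n_atoms=60, d_min=2.0,
                              tncs_vector=(0.5, 0.0, 0.0), noise_k=0.0)
        ds = simulate_dataset(cfg)
        norm = normalize(ds.reflections)
        res = l_test(norm, seed=2)
        assert res.mean_abs_L == pytest.approx(0.5, abs=0.015)
        # naive pairing oracle: neighbors along +h mix the strong/weak
        # tNCS-modulated classes and depress |L|
        df = norm.data
        lookup = {(r.h, r.k, r.l): r.E2 for r in df.itertuples()}
        l_naive = []
        for r in df.itertuples():
            mate = lookup.get((r.h + 1, r.k, r.l))
            if mate is not None and np.isfinite(r.E2) and np.isfinite(mate):
                tot = r.E2 + mate
                if tot > 0:
                    l_naive.append((r.E2 - mate) / tot)
        assert np.abs(np.mean(np.abs(l_naive)) - 0.5) > 0.05


class TestHTestAndBritton:
    @pytest.mark.parametrize("alpha", [0.0, 0.20])
    def test_alpha_recovery(self, p41_untwinned, p41_law, alpha):
        rs = twinned_set(p41_untwinned, p41_law, alpha)
        res = h_test(rs, p41_law)
        tol = 0.02 if alpha == 0.0 else 0.03
        assert res.alpha_mean == pytest.approx(alpha, abs=tol)

    def test_perfect_twin_limit(self, p41_untwinned, p41_law):
        rs = twinned_set(p41_untwinned, p41_law, 0.5)
        res = h_test(rs, p41_law)
        assert res.alpha_mean == pytest.approx(0.5, abs=1e-9)

    def test_britton_recovery(self, p41_untwinned, p41_law):
        rs = twinned_set(p41_untwinned, p41_law, 0.30)
        res = britton(rs, p41_law)
        assert res.alpha_estimate == pytest.approx(0.30, abs=0.05)
        assert np.all(np.diff(res.n_negative) >= 0)

    def test_britton_untwinned_with_noise(self, clean_p21):
        cfg = SyntheticConfig(seed=62, cell=(42, 42, 56, 90, 90, 90),
                              sg_symbol="P41", n_atoms=100, d_min=2.2,
                              noise_k=0.08)
        ds = simulate_dataset(cfg)
        law = candidate_twin_laws(ds.reflections.cell, ds.reflections.sg)[0]
        res = britton(ds.reflections, law)
        assert res.n_negative[1] > 0  # counts rise from the first trials
        assert res.alpha_estimate == pytest.approx(0.0, abs=0.03)

    def test_no_negatives_below_true_alpha(self, p41_untwinned, p41_law):
        rs = twinned_set(p41_untwinned, p41_law, 0.30)
        res = britton(rs, p41_law)
        below = res.alpha_grid < 0.28
        assert res.n_negative[below].sum() == 0


class TestDetwin:
    def test_hand_example(self):
        """I₁=80, I₂=20, α=0.25 → I₁′ = (0.75·80 − 0.25·20)/0.5 = 110."""
        cell = UnitCell(20, 24, 28)
        sg = parse_spacegroup("P1")
        from refltriage.twinning import TwinLaw
        law = TwinLaw(operator=np.diag([-1, -1, 1]), kind="user", description="test")
        rs = make_merged_set(np.array([[1, 2, 3], [1, 2, -3]]),
                             np.array([80.0, 20.0]), cell, sg,
                             sigI=np.array([1.0, 1.0]))
        out = detwin(rs, law, 0.25)
        assert out.data["I"].tolist() == pytest.approx([110.0, -10.0])

    def test_roundtrip_is_identity(self, p41_untwinned, p41_law):
        rs0 = p41_untwinned.reflections
        for alpha in (0.1, 0.45):
            tw = twinned_set(p41_untwinned, p41_law, alpha)
            back = detwin(tw, p41_law, alpha)
            np.testing.assert_allclose(back.data["I"], p41_untwinned.true_intensity,
                                       rtol=1e-9, atol=1e-9 * rs0.data["I"].abs().max())

    def test_alpha_zero_is_identity(self, clean_p21, p41_law):
        rs = clean_p21.reflections
        out = detwin(rs, p41_law, 0.0)
        np.testing.assert_array_equal(out.data["I"], rs.data["I"])

    def test_half_rejected(self, clean_p21, p41_law):
        with pytest.raises(ValueError, match="singular"):
            detwin(clean_p21.reflections, p41_law, 0.5)


class TestCorrelationAndMonotonicity:
    def test_untwinned_uncorrelated(self, p41_untwinned, p41_law):
        rs = twinned_set(p41_untwinned, p41_law, 0.0)
        res = twin_correlation(rs, p41_law)
        assert abs(res["correlation"]) < 0.1

    def test_perfect_twin_fully_correlated(self, p41_untwinned, p41_law):
        rs = twinned_set(p41_untwinned, p41_law, 0.5)
        res = twin_correlation(rs, p41_law)
        assert res["correlation"] == pytest.approx(1.0, abs=1e-9)
        assert res["r_augmented"] == pytest.approx(0.0, abs=1e-9)

    def test_higher_symmetry_relabelled_in_subgroup(self):
        """Data generated with 4-fold symmetry but labelled P2 shows perfect
        twin-law correlation with tiny augmented-symmetry R."""
        cfg = SyntheticConfig(seed=63, cell=(40, 40, 48, 90, 90, 90),
                              sg_symbol="P41", n_atoms=80, d_min=2.4, noise_k=0.01)
        ds = simulate_dataset(cfg)
        rs = ds.reflections
        # expand the tetragonal uniques to the lower-symmetry asymmetric unit
        from refltriage.patterson import _expand_to_sphere
        from refltriage.reflections import asu_map
        p1 = parse_spacegroup("P1")
        hkl_all, I_all = _expand_to_sphere(rs)
        keys = asu_map(hkl_all, p1, friedel=True)
        _, first = np.unique(keys, axis=0, return_index=True)
        relabelled = make_merged_set(hkl_all[first], I_all[first], rs.cell, p1)
        laws = candidate_twin_laws(relabelled.cell, relabelled.sg)
        best = max((twin_correlation(relabelled, lw)["correlation"] for lw in laws))
        assert best > 0.95

    def test_moment_ratio_decreases_with_alpha(self, p41_untwinned, p41_law):
        ratios = []
        for alpha in np.arange(0.0, 0.51, 0.1):
            rs = twinned_set(p41_untwinned, p41_law, min(alpha, 0.5))
            mom = moments(normalize(rs))
            ratios.append(mom.I2_over_I_sq_acentric)
        assert np.all(np.diff(ratios) < 0)
        assert ratios[0] == pytest.approx(2.0, abs=0.1)
        assert ratios[-1] == pytest.approx(1.5, abs=0.1)
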