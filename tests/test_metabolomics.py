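"""Feature-table normalization, ordination, per-feature tests, ion matching."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import make_feature_matrix
from rhizoface.config import MetabolomeSpec
from rhizoface.metabolomics import (
    classification_summary,
    normalize_and_scale,
    pca_ordination,
    per_feature_test,
    shared_features,
    signed_fold,
)
from rhizoface.synthetic import generate_feature_matrices


class TestNormalizeAndScale:
    def test_constant_feature_dropped_and_counted(self):
        fm = make_feature_matrix([[5, 5, 5], [1, 2, 3]], [[5, 5, 5], [4, 5, 6]])
        out, dropped = normalize_and_scale(fm)
        assert dropped == 1
        assert out.n_features == 1

    def test_retained_features_have_unit_variance(self):
        rng = np.random.default_rng(0)
        fm = make_feature_matrix(rng.lognormal(size=(20, 5)), rng.lognormal(size=(20, 5)))
        out, _ = normalize_and_scale(fm)
        np.testing.assert_allclose(out.abundance.std(axis=1), 1.0, atol=1e-12)
        np.testing.assert_allclose(out.abundance.mean(axis=1), 0.0, atol=1e-12)

    def test_zero_abundance_maps_to_zero_before_scaling(self):
        # pseudocount 1: ln(0/mass + 1) = 0 at unit mass
        fm = make_feature_matrix([[0.0, 1.0, 2.0]], [[3.0, 4.0, 5.0]])
        normed = np.log(fm.abundance + 1.0)
        assert normed[0, 0] == 0.0

    def test_mass_normalization_divides_by_root_mass(self):
        fm = make_feature_matrix([[8.0, 8.0]], [[8.0, 8.0]], masses=[2.0, 4.0, 8.0, 1.0])
        out, _ = normalize_and_scale(fm, pseudocount=1e-12)
        raw = fm.abundance[0] / np.array([2.0, 4.0, 8.0, 1.0])
        expect = (np.log(raw + 1e-12) - np.log(raw + 1e-12).mean()) / np.log(raw + 1e-12).std()
        np.testing.assert_allclose(out.abundance[0], expect)


class TestOrdination:
    def test_perfectly_correlated_features_one_axis(self):
        x = np.array([[1.0, 2, 3, 4], [2.0, 4, 6, 8]])
        fm = make_feature_matrix(x[:, :2], x[:, 2:])
        ord_ = pca_ordination(fm)
        assert ord_["explained_pct"][0] == pytest.approx(100.0)

    def test_explained_variance_sums_to_at_most_hundred(self):
        rng = np.random.default_rng(1)
        fm = make_feature_matrix(rng.normal(size=(6, 4)), rng.normal(size=(6, 4)))
        ord_ = pca_ordination(fm)
        pct = ord_["explained_pct"]
        assert np.all(np.diff(pct) <= 1e-9)  # non-increasing
        assert pct.sum() <= 100.0 + 1e-9

    def test_null_matrix_group_centroids_indistinguishable(self):
        rng = np.random.default_rng(2)
        fm = make_feature_matrix(rng.normal(size=(40, 9)), rng.normal(size=(40, 9)))
        ord_ = pca_ordination(fm, n_components=2)
        scores = ord_["scores"][["Dim1", "Dim2"]].to_numpy()
        labels = (ord_["scores"]["treatment"] == "elevated").to_numpy()
        obs = np.linalg.norm(scores[labels].mean(0) - scores[~labels].mean(0))
        perm = []
        for _ in range(999):
            lab = rng.permutation(labels)
            perm.append(np.linalg.norm(scores[lab].mean(0) - scores[~lab].mean(0)))
        p = (1 + np.sum(np.asarray(perm) >= obs)) / 1000
        assert p > 0.05

    def test_too_few_samples_rejected(self):
        fm = make_feature_matrix([[1.0], [2.0]], [[2.0], [1.0]])
        with pytest.raises(ValueError):
            pca_ordination(fm)


class TestPerFeatureTest:
    def test_kruskal_wallis_separated_triples(self):
        fm = make_feature_matrix([[4.0, 5.0, 6.0]], [[1.0, 2.0, 3.0]])
        res = per_feature_test(fm)
        assert res.iloc[0]["H"] == pytest.approx(3.857, abs=5e-4)
        assert res.iloc[0]["p_value"] == pytest.approx(0.0495, abs=5e-4)

    def test_matches_scipy_kruskal_on_random_features(self):
        rng = np.random.default_rng(3)
        e = rng.lognormal(size=(50, 6))
        a = rng.lognormal(size=(50, 7))
        fm = make_feature_matrix(e, a)
        res = per_feature_test(fm)
        for i in rng.choice(50, 12, replace=False):
            h_ref, p_ref = sps.kruskal(e[i], a[i])
            assert res.iloc[int(i)]["H"] == pytest.approx(h_ref, rel=1e-9)
            assert res.iloc[int(i)]["p_value"] == pytest.approx(p_ref, rel=1e-9)

    def test_identical_groups_unchanged(self):
        fm = make_feature_matrix([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        res = per_feature_test(fm)
        assert res.iloc[0]["class"] == "unchanged"

    def test_degenerate_all_ties_p_one(self):
        fm = make_feature_matrix([[2.0, 2.0, 2.0]], [[2.0, 2.0, 2.0]])
        res = per_feature_test(fm)
        assert res.iloc[0]["p_value"] == 1.0

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        e, a = rng.lognormal(size=(20, 8)), rng.lognormal(size=(20, 8))
        p1 = per_feature_test(make_feature_matrix(e, a))["p_value"]
        p2 = per_feature_test(make_feature_matrix(e**3, a**3))["p_value"]
        np.testing.assert_allclose(p1, p2)

    def test_classification_partition(self):
        rng = np.random.default_rng(5)
        e = rng.lognormal(size=(100, 10))
        e[:20] *= 50.0
        a = rng.lognormal(size=(100, 10))
        res = per_feature_test(make_feature_matrix(e, a))
        s = classification_summary(res)
        assert s["n_accumulated"] + s["n_depleted"] == s["n_significant"]
        assert (res.loc[res["class"] == "accumulated", "signed_fold"] >= 1).all()
        assert (res.loc[res["class"] == "depleted", "signed_fold"] <= -1).all()

    def test_fdr_flag_shrinks_significant_set(self):
        rng = np.random.default_rng(6)
        fm = make_feature_matrix(rng.lognormal(size=(300, 8)), rng.lognormal(size=(300, 8)))
        raw = classification_summary(per_feature_test(fm))["n_significant"]
        adj = classification_summary(per_feature_test(fm, fdr=True))["n_significant"]
        assert adj <= raw

    def test_power_at_threefold_effect(self):
        # |fold| = 3 with log-noise 0.3 and n = 18/group should almost always be caught
        rng = np.random.default_rng(7)
        n_aff, n_null, n = 60, 140, 18
        base = np.exp(rng.normal(np.log(1e4), 1.0, n_aff + n_null))
        noise = np.exp(rng.normal(0, 0.3, (n_aff + n_null, 2 * n)))
        vals = base[:, None] * noise
        vals[:n_aff, :n] *= 3.0  # elevated accumulated three-fold
        fm = make_feature_matrix(vals[:, :n], vals[:, n:])
        res = per_feature_test(fm)
        detected = (res.iloc[:n_aff]["class"] == "accumulated").mean()
        assert detected >= 0.90


class TestSignedFold:
    @pytest.mark.parametrize("e, a, expected", [(2.0, 1.0, 2.0), (0.5, 1.0, -2.0), (1.0, 1.0, 1.0)])
    def test_convention(self, e, a, expected):
        assert signed_fold(e, a) == pytest.approx(expected)

    def test_swap_antisymmetry(self):
        # the signed convention makes a swap negate the fold: r and 1/r map
        # to +r and -r
        rng = np.random.default_rng(8)
        for _ in range(50):
            e, a = rng.uniform(0.1, 10, 2)
            if abs(e / a - 1) < 1e-9:
                continue
            assert signed_fold(e, a) == pytest.approx(-signed_fold(a, e))

    def test_zero_rejected(self):
        with pytest.raises(ValueError):
            signed_fold(0.0, 1.0)


class TestSharedFeatures:
    def test_identical_keys_all_matched(self):
        spec = MetabolomeSpec(n_features=50, shared_fraction=1.0, affected_fraction=0.0)
        roots, exudates, _ = generate_feature_matrices(spec, seed=1)
        out = shared_features(roots, exudates)
        assert out["n_shared"] == 50
        assert out["n_root_exclusive"] == 0 and out["n_exudate_exclusive"] == 0

    def test_offset_beyond_tolerance_unmatched(self):
        fm_a = make_feature_matrix([[1.0, 2.0]], [[1.0, 2.0]])
        fm_b = make_feature_matrix([[1.0, 2.0]], [[1.0, 2.0]])
        fm_b.features.loc[0, "mz"] *= 1 + 50e-6  # 50 ppm off
        out = shared_features(fm_a, fm_b, mz_tol_ppm=10.0)
        assert out["n_shared"] == 0

    def test_different_modes_never_compared(self):
        fm_a = make_feature_matrix([[1.0, 2.0]], [[1.0, 2.0]])
        fm_b = make_feature_matrix([[1.0, 2.0]], [[1.0, 2.0]])
        fm_b.features.loc[0, "mode"] = "negative"
        assert shared_features(fm_a, fm_b)["n_shared"] == 0

    def test_generator_shared_fraction_contract(self):
        spec = MetabolomeSpec(n_features=200, shared_fraction=0.4, affected_fraction=0.0)
        roots, exudates, _ = generate_feature_matrices(spec, seed=2)
        out = shared_features(roots, exudates)
        assert out["n_shared"] == round(0.4 * 200)
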