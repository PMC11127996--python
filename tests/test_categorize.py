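"""Five-category classification, its sub-statistics, and concordance."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from brainlipidome.categorize import (
    anova_region,
    category_concordance,
    classify_lipids,
    gaussian_threshold,
    myelin_model,
    profile_null_correlation,
    region_profiles,
    within_region_variability,
    wm_gm_fisher_validation,
)
from brainlipidome.stats import hypergeom_over


def _meta(regions, individuals):
    samples = [f"{r}_{i}" for r in regions for i in individuals]
    return pd.DataFrame({
        "region_id": [r for r in regions for _ in individuals],
        "individual_id": [i for _ in regions for i in individuals],
        "sample_type": "tissue",
    }, index=pd.Index(samples, name="sample_id"))


class TestAnova:
    def test_hand_computed_two_region_example(self):
        # groups {1,2} and {3,5}: SSB = 6.25, SSW = 2.5, F = 6.25/(2.5/2) = 5
        meta = _meta(["R1", "R2"], ["I1", "I2"])
        mat = pd.DataFrame([[1.0, 2.0, 3.0, 5.0]], columns=meta.index,
                           index=["lip"])
        res = anova_region(mat, meta)
        assert res.loc["lip", "F"] == pytest.approx(5.0)
        f_ref, p_ref = sps.f_oneway([1.0, 2.0], [3.0, 5.0])
        assert res.loc["lip", "p"] == pytest.approx(p_ref)

    def test_region_constant_zero_noise_p_zero(self):
        meta = _meta(["R1", "R2", "R3"], ["I1", "I2"])
        vals = {"R1": 0.0, "R2": 0.0, "R3": 1.0}
        mat = pd.DataFrame(
            [[vals[meta.loc[s, "region_id"]] for s in meta.index]],
            columns=meta.index, index=["lip"])
        res = anova_region(mat, meta)
        assert res.loc["lip", "p"] == 0.0

    def test_single_replicate_everywhere_error(self):
        meta = _meta(["R1", "R2"], ["I1"])
        mat = pd.DataFrame([[1.0, 2.0]], columns=meta.index)
        with pytest.raises(ValueError, match="replication"):
            anova_region(mat, meta)

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(8)
        meta = _meta([f"R{i}" for i in range(6)], ["I1", "I2", "I3"])
        mat = pd.DataFrame(rng.normal(size=(20, len(meta))),
                           columns=meta.index)
        res = anova_region(mat, meta)
        groups = meta.groupby("region_id").groups
        for lip in mat.index:
            f_ref, p_ref = sps.f_oneway(
                *[mat.loc[lip, list(cols)] for cols in groups.values()])
            assert res.loc[lip, "F"] == pytest.approx(f_ref)
            assert res.loc[lip, "p"] == pytest.approx(p_ref)


class TestMyelinModel:
    def test_exact_linear_profile(self):
        myelin = pd.Series([1.0, 1.5, 2.0, 1.2], index=list("abcd"))
        prof = pd.DataFrame([2 * myelin], index=["lip"])
        res = myelin_model(prof, myelin)
        assert res.loc["lip", "myelin_slope"] == pytest.approx(2.0)
        assert res.loc["lip", "myelin_p"] == 0.0

    def test_orthogonal_profile_zero_slope(self):
        myelin = pd.Series([1.0, 2.0, 1.0, 2.0], index=list("abcd"))
        prof = pd.DataFrame([[1.0, 1.0, -1.0, -1.0]], index=["lip"],
                            columns=list("abcd"))
        res = myelin_model(prof, myelin)
        assert res.loc["lip", "myelin_slope"] == pytest.approx(0.0)

    def test_matches_linregress(self):
        rng = np.random.default_rng(9)
        myelin = pd.Series(rng.uniform(1, 2, 8),
                           index=[f"R{i}" for i in range(8)])
        prof = pd.DataFrame(rng.normal(size=(5, 8)), columns=myelin.index)
        res = myelin_model(prof, myelin)
        for lip in prof.index:
            ref = sps.linregress(myelin, prof.loc[lip])
            assert res.loc[lip, "myelin_slope"] == pytest.approx(ref.slope)
            assert res.loc[lip, "myelin_p"] == pytest.approx(ref.pvalue)

    def test_constant_myelin_error(self):
        myelin = pd.Series([1.0, 1.0, 1.0], index=list("abc"))
        prof = pd.DataFrame([[1.0, 2.0, 3.0]], columns=list("abc"))
        with pytest.raises(ValueError, match="constant"):
            myelin_model(prof, myelin)


class TestWithinRegionVariability:
    def test_zero_noise_zero(self):
        meta = _meta(["R1", "R2"], ["I1", "I2"])
        mat = pd.DataFrame([[1.0, 1.0, 4.0, 4.0]], columns=meta.index)
        assert within_region_variability(mat, meta).iloc[0] == 0.0

    def test_region_offset_invariance(self):
        rng = np.random.default_rng(10)
        meta = _meta([f"R{i}" for i in range(5)], ["I1", "I2", "I3"])
        mat = pd.DataFrame(rng.normal(size=(4, len(meta))),
                           columns=meta.index)
        base = within_region_variability(mat, meta)
        offsets = {f"R{i}": rng.normal() * 10 for i in range(5)}
        shifted = mat + np.array(
            [offsets[meta.loc[s, "region_id"]] for s in meta.index])
        pd.testing.assert_series_equal(
            base, within_region_variability(shifted, meta))

    def test_consistency_for_iid_noise(self):
        rng = np.random.default_rng(11)
        meta = _meta([f"R{i}" for i in range(60)], [f"I{k}" for k in range(8)])
        sigma = 0.7
        mat = pd.DataFrame(rng.normal(0, sigma, size=(3, len(meta))),
                           columns=meta.index)
        est = within_region_variability(mat, meta)
        assert est.to_numpy() == pytest.approx(sigma, rel=0.1)


class TestGaussianThreshold:
    def test_normal_recovery(self):
        rng = np.random.default_rng(12)
        v = rng.normal(1.0, 0.2, 10_000)
        assert gaussian_threshold(v) == pytest.approx(1.2, abs=0.02)

    def test_contamination_tracks_bulk(self):
        rng = np.random.default_rng(13)
        bulk = rng.normal(1.0, 0.2, 9_500)
        tail = rng.uniform(3, 10, 500)
        thr = gaussian_threshold(np.concatenate([bulk, tail]))
        assert thr == pytest.approx(1.2, abs=0.05)

    def test_constant_input(self):
        assert gaussian_threshold([2.0] * 12) == 2.0

    def test_too_few_values(self):
        with pytest.raises(ValueError):
            gaussian_threshold([1.0] * 9)

    def test_mixture_method(self):
        rng = np.random.default_rng(14)
        v = np.concatenate([rng.normal(1.0, 0.2, 2000),
                            rng.normal(5.0, 0.5, 300)])
        assert gaussian_threshold(v, method="mixture") == pytest.approx(
            1.2, abs=0.1)


class TestClassify:
    def test_constant_lipid_is_housekeeping(self):
        rng = np.random.default_rng(15)
        meta = _meta([f"R{i}" for i in range(20)], ["I1", "I2", "I3", "I4"])
        region_meta = pd.DataFrame(
            {"myelin": rng.uniform(1, 2, 20)},
            index=[f"R{i}" for i in range(20)])
        quiet = rng.normal(0, 0.01, (12, len(meta)))
        mat = pd.DataFrame(quiet, columns=meta.index,
                           index=[f"hk{i}" for i in range(12)])
        res = classify_lipids(mat, meta, region_meta)
        assert (res["category"] == "housekeeping").sum() >= 11

    def test_partition_and_reordering_invariance(self, small_atlas,
                                                 small_normalized):
        meta = small_atlas.sample_meta
        rm = small_atlas.region_meta
        res = classify_lipids(small_normalized, meta, rm)
        assert res["category"].notna().all()
        assert res["category"].isin(
            ["myelin_pos", "myelin_neg", "unexplained", "housekeeping",
             "variable"]).all()
        rng = np.random.default_rng(16)
        shuffled = small_normalized.iloc[
            rng.permutation(len(small_normalized))]
        res2 = classify_lipids(shuffled, meta, rm)
        pd.testing.assert_series_equal(res["category"].sort_index(),
                                       res2["category"].sort_index())

    def test_region_relabel_equivariance(self, small_atlas,
                                         small_normalized):
        meta = small_atlas.sample_meta
        rm = small_atlas.region_meta
        res = classify_lipids(small_normalized, meta, rm)
        mapping = {r: f"X{r}" for r in rm.index}
        meta2 = meta.assign(region_id=meta["region_id"].map(mapping))
        rm2 = rm.rename(index=mapping)
        res2 = classify_lipids(small_normalized, meta2, rm2)
        pd.testing.assert_series_equal(res["category"], res2["category"])

    def test_small_atlas_recovery(self, small_atlas, small_normalized):
        res = classify_lipids(small_normalized, small_atlas.sample_meta,
                              small_atlas.region_meta)
        truth = small_atlas.truth_lipids
        acc = (res["category"] == truth["category"]).mean()
        assert acc >= 0.9
        # sign confusion between myelin+ and myelin- never happens
        mp = truth.index[truth["category"] == "myelin_pos"]
        mn = truth.index[truth["category"] == "myelin_neg"]
        assert not (res.loc[mp, "category"] == "myelin_neg").any()
        assert not (res.loc[mn, "category"] == "myelin_pos").any()


class TestProfileNull:
    def _profiles(self, seed, n_lipids=20, n_regions=12):
        rng = np.random.default_rng(seed)
        return pd.DataFrame(rng.normal(size=(n_lipids, n_regions)),
                            index=[f"L{i}" for i in range(n_lipids)],
                            columns=[f"R{i}" for i in range(n_regions)])

    def test_self_comparison(self):
        a = self._profiles(17)
        true_r, null, test = profile_null_correlation(a, a, n_perm=200,
                                                      seed=0)
        assert np.allclose(true_r, 1.0)
        assert test.p < 1e-3

    def test_independent_datasets_similar_distributions(self):
        a = self._profiles(18)
        b = self._profiles(19)
        true_r, null, test = profile_null_correlation(a, b, n_perm=200,
                                                      seed=0)
        assert abs(true_r.mean() - null.to_numpy().mean()) < 0.15

    def test_seed_reproducibility(self):
        a = self._profiles(20)
        b = self._profiles(21)
        r1 = profile_null_correlation(a, b, n_perm=50, seed=5)
        r2 = profile_null_correlation(a, b, n_perm=50, seed=5)
        pd.testing.assert_frame_equal(r1[1], r2[1])

    def test_too_few_regions(self):
        a = self._profiles(22, n_regions=2)
        with pytest.raises(ValueError):
            profile_null_correlation(a, a)


class TestConcordance:
    def _result(self, cats, anova_ps):
        return pd.DataFrame({"category": cats, "anova_p_adj": anova_ps},
                            index=[f"L{i}" for i in range(len(cats))])

    def test_three_outcomes(self):
        a = self._result(["myelin_pos", "myelin_pos", "myelin_pos"],
                         [0.001, 0.001, 0.001])
        b = self._result(["myelin_pos", "housekeeping", "myelin_neg"],
                         [0.001, 0.5, 0.001])
        out = category_concordance(a, b)
        assert list(out) == ["good", "neutral", "bad"]

    def test_missing_lipid_counted(self):
        a = self._result(["myelin_pos", "variable"], [0.001, 0.8])
        b = self._result(["myelin_pos"], [0.001]).iloc[:1]
        out = category_concordance(a, b)
        assert len(out) == 1 and out.attrs["n_excluded"] == 1


class TestFisherValidation:
    def test_concordant_table_matches_enumeration(self):
        # 10 white-enriched myelin+ and 10 gray-enriched myelin-
        cats = pd.Series(["myelin_pos"] * 10 + ["myelin_neg"] * 10,
                         index=[f"L{i}" for i in range(20)])
        de = pd.DataFrame({
            "log10_diff": [1.0] * 10 + [-1.0] * 10,
            "p_adj": 0.001,
        }, index=cats.index)
        res, table = wm_gm_fisher_validation(de, cats)
        assert table.tolist() == [[10, 0], [0, 10]]
        # oracle: hypergeometric enumeration of the two-sided tail
        p_oracle = 2 * hypergeom_over(10, 10, 10, 20)
        assert res.p == pytest.approx(p_oracle, rel=1e-9)

    def test_thresholds_applied(self):
        cats = pd.Series(["myelin_pos", "myelin_neg"], index=["a", "b"])
        de = pd.DataFrame({"log10_diff": [0.1, 1.0], "p_adj": [0.001, 0.5]},
                          index=["a", "b"])
        res, table = wm_gm_fisher_validation(de, cats)
        assert res is None and table.sum() == 0
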