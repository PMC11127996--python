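"""Imputation, QC filters and the normalization cascade."""

import numpy as np
import pandas as pd
import pytest

from brainlipidome.preprocess import (
    IntensityMatrix,
    blank_filter,
    impute_missing,
    mrm_qc_filter,
    normalize_expression,
    normalize_intensities,
    qc_cv_filter,
    replay,
)


def _meta(samples, types, batches=None, dilutions=None, regions=None,
          individuals=None):
    n = len(samples)
    return pd.DataFrame({
        "region_id": regions or [f"R{i}" for i in range(n)],
        "individual_id": individuals or ["I1"] * n,
        "sample_type": types,
        "wet_weight_mg": 10.0,
        "batch_id": batches or ["B1"] * n,
        "dilution_factor": dilutions if dilutions is not None
        else [np.nan] * n,
    }, index=pd.Index(samples, name="sample_id"))


class TestImpute:
    def test_no_missing_identity(self):
        df = pd.DataFrame(np.ones((3, 4)) * 5.0,
                          index=list("abc"), columns=list("wxyz"))
        out = impute_missing(IntensityMatrix(df), seed=0)
        pd.testing.assert_frame_equal(out.data, df)
        assert out.stage == "imputed"

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.uniform(10, 100, (20, 10)))
        df.iloc[rng.random((20, 10)) < 0.2] = np.nan
        a = impute_missing(IntensityMatrix(df.copy()), seed=3).data
        b = impute_missing(IntensityMatrix(df.copy()), seed=3).data
        c = impute_missing(IntensityMatrix(df.copy()), seed=4).data
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_fill_distribution_matches_model(self):
        # realistic detection floors spanning orders of magnitude: the 16th
        # percentile (the sigma of the fill model) is well below the median,
        # so zero-truncation is negligible and fills centre on median(D)
        rng = np.random.default_rng(1)
        n_lipids = 200
        minima = 10 ** np.linspace(2, 4, n_lipids)
        data = minima[:, None] * rng.uniform(1, 3, (n_lipids, 100))
        data[:, 0] = minima  # pin the per-lipid minimum
        df = pd.DataFrame(data)
        df.iloc[:, 50:] = np.nan  # half the cells missing, 10^4 fills
        out = impute_missing(IntensityMatrix(df), seed=2).data
        fills = out.iloc[:, 50:].to_numpy().ravel()
        mu = np.median(minima)
        sigma = np.percentile(minima, 16)
        assert fills.mean() == pytest.approx(mu, abs=3 * sigma / 100)
        assert fills.std() == pytest.approx(sigma, rel=0.05)
        assert (fills >= 0).all()

    def test_all_missing_lipid_named(self):
        df = pd.DataFrame([[1.0, 2.0], [np.nan, 0.0]],
                          index=["ok", "deadlipid"])
        with pytest.raises(ValueError, match="deadlipid"):
            impute_missing(IntensityMatrix(df), seed=0)


class TestBlankFilter:
    def test_two_fold_rule(self):
        df = pd.DataFrame({"t1": [100.0, 100.0], "t2": [100.0, 100.0],
                           "bl": [51.0, 50.0]}, index=["drop", "keep"])
        meta = _meta(["t1", "t2", "bl"], ["tissue", "tissue", "blank"])
        out = blank_filter(IntensityMatrix(df), meta)
        assert list(out.data.index) == ["keep"]

    def test_zero_blank_kept(self):
        df = pd.DataFrame({"t1": [5.0], "bl": [0.0]}, index=["a"])
        meta = _meta(["t1", "bl"], ["tissue", "blank"])
        assert len(blank_filter(IntensityMatrix(df), meta).data) == 1

    def test_no_blanks_error(self):
        df = pd.DataFrame({"t1": [5.0]}, index=["a"])
        with pytest.raises(ValueError):
            blank_filter(IntensityMatrix(df), _meta(["t1"], ["tissue"]))

    def test_survivor_count_equals_recount(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.uniform(1, 100, (50, 6)),
                          columns=[f"s{i}" for i in range(6)])
        meta = _meta(df.columns, ["tissue"] * 4 + ["blank"] * 2)
        out = blank_filter(IntensityMatrix(df), meta)
        brute = sum(
            df.iloc[i, :4].mean() >= 2 * df.iloc[i, 4:].mean()
            for i in range(len(df))
        )
        assert len(out.data) == brute


class TestQcCvFilter:
    def _matrix(self, qc_values):
        # three batches x 3 QC samples, plus tissue columns
        cols = [f"q{b}{i}" for b in range(3) for i in range(3)]
        df = pd.DataFrame([qc_values], columns=cols, index=["lip"])
        types = ["QC"] * 9
        batches = [f"B{b}" for b in range(3) for _ in range(3)]
        return df, _meta(cols, types, batches=batches)

    def test_constant_qc_kept(self):
        df, meta = self._matrix([10.0] * 9)
        assert len(qc_cv_filter(IntensityMatrix(df), meta).data) == 1

    def test_median_over_batches(self):
        # batch CoVs ~ {0.1, 0.1, 0.5}: median 0.1 < 0.25 -> kept
        vals = [10, 11, 9, 10, 11, 9, 10, 20, 3]
        df, meta = self._matrix([float(v) for v in vals])
        out = qc_cv_filter(IntensityMatrix(df), meta)
        assert len(out.data) == 1

    def test_all_batches_high_cv_dropped(self):
        vals = [10.0, 20.0, 3.0] * 3
        df, meta = self._matrix(vals)
        assert len(qc_cv_filter(IntensityMatrix(df), meta).data) == 0

    def test_single_qc_batch_excluded_with_warning(self):
        df = pd.DataFrame({"q1": [10.0], "q2": [10.5], "q3": [30.0]},
                          index=["lip"])
        meta = _meta(["q1", "q2", "q3"], ["QC"] * 3,
                     batches=["B1", "B1", "B2"])
        with pytest.warns(UserWarning, match="B2"):
            out = qc_cv_filter(IntensityMatrix(df), meta)
        assert len(out.data) == 1  # B2's lone QC not counted


class TestMrmFilter:
    def _setup(self, blank_level=1.0, diqc_slope=1.0, diqc_noise=0.0):
        rng = np.random.default_rng(0)
        dils = [0.0625, 0.125, 0.25, 0.5, 1.0] * 2
        cols = (["t1", "t2", "bl", "q1", "q2"]
                + [f"d{i}" for i in range(10)])
        tissue = [100.0, 102.0]
        qc = [100.0, 101.0]
        diqc = [100.0 * d ** diqc_slope
                * 10 ** rng.normal(0, diqc_noise) for d in dils]
        df = pd.DataFrame([tissue + [blank_level] + qc + diqc],
                          columns=cols, index=["tr1"])
        meta = _meta(cols, ["tissue", "tissue", "blank", "QC", "QC"]
                     + ["DiQC"] * 10,
                     dilutions=[np.nan] * 5 + dils)
        return IntensityMatrix(df), meta

    def test_linear_dilution_passes(self):
        m, meta = self._setup()
        out, report = mrm_qc_filter(m, meta)
        assert len(out.data) == 1
        assert report.loc["tr1", ["pass_blank", "pass_cv",
                                  "pass_diqc"]].all()

    def test_blank_above_tenth_excluded(self):
        m, meta = self._setup(blank_level=20.0)  # 0.2x of ~101 mean
        out, report = mrm_qc_filter(m, meta)
        assert len(out.data) == 0 and not report.loc["tr1", "pass_blank"]

    def test_flat_dilution_response_excluded(self):
        m, meta = self._setup(diqc_slope=0.0, diqc_noise=0.05)
        out, report = mrm_qc_filter(m, meta)
        assert not report.loc["tr1", "pass_diqc"]

    def test_missing_diqc_skips_third_test(self):
        m, meta = self._setup()
        meta2 = meta[meta["sample_type"] != "DiQC"]
        m2 = IntensityMatrix(m.data[meta2.index])
        with pytest.warns(UserWarning, match="DiQC"):
            out, report = mrm_qc_filter(m2, meta2)
        assert report["diqc_skipped"].all()
        assert len(out.data) == 1

    def test_pass_count_is_test_intersection(self):
        rng = np.random.default_rng(3)
        dils = [0.0625, 0.125, 0.25, 0.5, 1.0] * 2
        cols = ["t1", "t2", "bl", "q1", "q2"] + [f"d{i}" for i in range(10)]
        n = 40
        data = np.column_stack([
            rng.uniform(50, 150, (n, 2)),
            rng.uniform(0, 30, (n, 1)),
            rng.uniform(90, 130, (n, 2)),
            rng.uniform(10, 200, (n, 10)),
        ])
        df = pd.DataFrame(data, columns=cols)
        meta = _meta(cols, ["tissue", "tissue", "blank", "QC", "QC"]
                     + ["DiQC"] * 10, dilutions=[np.nan] * 5 + dils)
        out, report = mrm_qc_filter(IntensityMatrix(df), meta)
        expected = (report["pass_blank"] & report["pass_cv"]
                    & report["pass_diqc"]).sum()
        assert len(out.data) == expected


class TestNormalizeIntensities:
    def _meta2(self):
        return _meta(["s1", "s2"], ["tissue", "tissue"],
                     regions=["R1", "R2"], individuals=["I1", "I1"])

    def test_centering_example(self):
        df = pd.DataFrame({"s1": [1e5], "s2": [1e7]}, index=["lip"])
        std = pd.Series(1.0, index=["s1", "s2"])
        out = normalize_intensities(IntensityMatrix(df), self._meta2(), std)
        assert out.data.loc["lip"].to_numpy() == pytest.approx([-1.0, 1.0])

    def test_wet_weight_shift_invariance(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.uniform(1e4, 1e6, (5, 2)),
                          columns=["s1", "s2"])
        std = pd.Series([2.0, 3.0], index=["s1", "s2"])
        meta = self._meta2()
        a = normalize_intensities(IntensityMatrix(df.copy()), meta, std).data
        meta2 = meta.assign(wet_weight_mg=meta["wet_weight_mg"] * 2)
        b = normalize_intensities(IntensityMatrix(df.copy()), meta2, std).data
        pd.testing.assert_frame_equal(a, b)

    def test_scaling_absorbed_by_standards(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.uniform(1e4, 1e6, (5, 2)),
                          columns=["s1", "s2"])
        std = pd.Series([2.0, 3.0], index=["s1", "s2"])
        meta = self._meta2()
        a = normalize_intensities(IntensityMatrix(df.copy()), meta, std).data
        df2 = df.copy()
        df2["s1"] *= 10
        b = normalize_intensities(IntensityMatrix(df2), meta,
                                  std * pd.Series({"s1": 10.0, "s2": 1.0})
                                  ).data
        pd.testing.assert_frame_equal(a, b)

    def test_per_individual_means_zero(self, small_atlas, small_normalized):
        meta = small_atlas.sample_meta
        for ind, cols in meta.groupby("individual_id").groups.items():
            assert np.allclose(small_normalized[list(cols)].mean(axis=1),
                               0.0, atol=1e-12)

    def test_nonpositive_intensity_error(self):
        df = pd.DataFrame({"s1": [0.0], "s2": [10.0]})
        with pytest.raises(ValueError, match="impute|nonpositive"):
            normalize_intensities(IntensityMatrix(df), self._meta2(),
                                  pd.Series(1.0, index=["s1", "s2"]))

    def test_missing_weight_error(self):
        df = pd.DataFrame({"s1": [10.0], "s2": [10.0]})
        meta = self._meta2().assign(wet_weight_mg=[np.nan, 10.0])
        with pytest.raises(ValueError, match="weight"):
            normalize_intensities(IntensityMatrix(df), meta,
                                  pd.Series(1.0, index=["s1", "s2"]))


class TestNormalizeExpression:
    def _meta(self, cols):
        return pd.DataFrame({
            "region_id": [f"R{i}" for i in range(len(cols))],
            "individual_id": ["I1"] * len(cols),
        }, index=pd.Index(cols, name="sample_id"))

    def test_low_tpm_gene_removed(self):
        tpm = pd.DataFrame({"s1": [0.5, 10.0], "s2": [0.5, 20.0]},
                           index=["low", "high"])
        out = normalize_expression(tpm, self._meta(tpm.columns))
        assert list(out.index) == ["high"]

    def test_constant_gene_all_zero(self):
        tpm = pd.DataFrame({"s1": [10.0], "s2": [10.0], "s3": [10.0]},
                           index=["g"])
        out = normalize_expression(tpm, self._meta(tpm.columns))
        assert np.allclose(out.loc["g"], 0.0)

    def test_per_individual_gene_means_zero(self):
        rng = np.random.default_rng(4)
        cols = [f"s{i}" for i in range(8)]
        tpm = pd.DataFrame(rng.uniform(2, 100, (10, 8)), columns=cols)
        meta = self._meta(cols)
        meta["individual_id"] = ["I1"] * 4 + ["I2"] * 4
        out = normalize_expression(tpm, meta)
        for ind, cidx in meta.groupby("individual_id").groups.items():
            assert np.allclose(out[list(cidx)].mean(axis=1), 0.0, atol=1e-12)

    def test_protein_coding_gate(self):
        tpm = pd.DataFrame({"s1": [10.0, 10.0], "s2": [20.0, 30.0]},
                           index=["coding", "lnc"])
        coding = pd.Series({"coding": True, "lnc": False})
        out = normalize_expression(tpm, self._meta(tpm.columns),
                                   protein_coding=coding)
        assert list(out.index) == ["coding"]


class TestFilterAlgebra:
    def test_blank_and_cv_filters_commute(self):
        rng = np.random.default_rng(11)
        cols = ["t1", "t2", "t3", "bl", "q1", "q2", "q3"]
        df = pd.DataFrame(rng.uniform(1, 100, (60, 7)), columns=cols)
        meta = _meta(cols, ["tissue"] * 3 + ["blank"] + ["QC"] * 3)
        m = IntensityMatrix(df)
        ab = qc_cv_filter(blank_filter(m, meta), meta).data.index
        ba = blank_filter(qc_cv_filter(m, meta), meta).data.index
        assert list(ab) == list(ba)

    def test_replay_reproduces_bit_for_bit(self):
        rng = np.random.default_rng(12)
        cols = ["t1", "t2", "bl", "q1", "q2"]
        df = pd.DataFrame(rng.uniform(10, 100, (30, 5)), columns=cols)
        df.iloc[rng.random((30, 5)) < 0.1] = np.nan
        df[["bl", "q1", "q2"]] = df[["bl", "q1", "q2"]].fillna(1.0)
        meta = _meta(cols, ["tissue", "tissue", "blank", "QC", "QC"],
                     regions=["R1", "R2", "x", "x", "x"],
                     individuals=["I1"] * 5)
        std = pd.Series(1.0, index=cols)
        m = impute_missing(IntensityMatrix(df.copy()), seed=5)
        m = blank_filter(m, meta)
        m = normalize_intensities(m, meta, std)
        redo = replay(IntensityMatrix(df.copy()), meta, std, m.provenance)
        pd.testing.assert_frame_equal(m.data, redo.data)
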