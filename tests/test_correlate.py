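import numpy as np
import pandas as pd
import pytest

import doseagree as da
from doseagree.errors import DegenerateInputError
from _oracles import ols_from_sums


class TestOlsR2:
    def test_perfect_affine_fit(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        r2, p = da.ols_r2(x, 2 * x + 1)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert p < 1e-6

    def test_symmetric_pattern_has_zero_slope(self):
        r2, p = da.ols_r2(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 2, 1]))
        assert r2 == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-9)

    def test_matches_sums_of_squares_oracle(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=10)
        y = 1.3 * x + rng.normal(scale=0.5, size=10)
        r2, p = da.ols_r2(x, y)
        r2_o, p_o = ols_from_sums(x, y)
        assert r2 == pytest.approx(r2_o, abs=1e-10)
        assert p == pytest.approx(p_o, abs=1e-10)

    def test_matches_statsmodels(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(21)
        x = rng.uniform(0, 100, 30)
        y = 0.7 * x + rng.normal(scale=5.0, size=30)
        r2, p = da.ols_r2(x, y)
        fit = sm.OLS(y, sm.add_constant(x)).fit()
        assert r2 == pytest.approx(fit.rsquared, abs=1e-10)
        assert p == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_direction_independence_of_r2(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=25)
        y = x + rng.normal(scale=0.3, size=25)
        assert da.ols_r2(x, y)[0] == pytest.approx(da.ols_r2(y, x)[0], abs=1e-10)

    def test_constant_x_is_undefined(self):
        with pytest.raises(DegenerateInputError):
            da.ols_r2(np.ones(5), np.arange(5.0))

    def test_constant_y_returns_zero_by_convention(self):
        assert da.ols_r2(np.arange(5.0), np.ones(5)) == (0.0, 1.0)

    def test_too_few_points(self):
        with pytest.raises(DegenerateInputError):
            da.ols_r2(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestSidak:
    def test_single_comparison_is_uncorrected(self):
        assert da.sidak_correct(0.05, 1) == pytest.approx(0.05, abs=1e-15)

    def test_ten_comparisons_closed_form(self):
        assert da.sidak_correct(0.05, 10) == pytest.approx(1 - 0.95 ** 0.1, abs=1e-15)

    def test_monotone_decreasing_in_family_size(self):
        levels = [da.sidak_correct(0.05, m) for m in (1, 2, 5, 10, 100)]
        assert all(a > b for a, b in zip(levels, levels[1:]))

    @pytest.mark.parametrize("m", [2, 5, 17])
    def test_between_bonferroni_and_uncorrected(self, m):
        level = da.sidak_correct(0.05, m)
        assert 0.05 / m < level < 0.05


class TestBatchIndices:
    def test_table_shape_and_columns(self):
        pairs = da.cohort_pairs(n=2, errored_fraction=0.5, seed=4)
        table = da.batch_indices(pairs, ("gamma_global",), [(2.0, 2.0)], [10.0])
        assert table.data.shape == (2, 1)
        assert table.data.columns.tolist() == [("gamma_global", 2.0, 2.0, 10.0)]
        assert table.labels.tolist() == [p[3] for p in pairs]

    def test_clean_cohort_summary_is_degenerate(self):
        pairs = da.cohort_pairs(n=3, errored_fraction=0.0, seed=5)
        table = da.batch_indices(pairs, ("gamma_global",), [(3.0, 3.0)], [10.0])
        summary = table.summary()
        assert summary["mean"].iloc[0] == 100.0
        assert summary["sd"].iloc[0] == 0.0

    def test_dnc_only_defined_at_ten_percent_threshold(self):
        pairs = da.cohort_pairs(n=2, errored_fraction=0.5, seed=6)
        table = da.batch_indices(pairs, ("dnc",), [(2.0, 2.0)], [5.0, 10.0])
        assert table.data[("dnc", 2.0, 2.0, 5.0)].isna().all()
        assert table.data[("dnc", 2.0, 2.0, 10.0)].notna().all()

    def test_manifest_round_trip_matches_in_memory(self, tmp_path):
        da.generate_cohort(3, 0.34, 8, tmp_path / "c")
        manifest = da.CohortManifest.from_tsv(tmp_path / "c" / "manifest.tsv")
        from_disk = da.batch_indices(manifest, ("gamma_global",), [(2.0, 2.0)], [10.0])
        in_mem = da.batch_indices(
            da.cohort_pairs(n=3, errored_fraction=0.34, seed=8),
            ("gamma_global",),
            [(2.0, 2.0)],
            [10.0],
        )
        np.testing.assert_allclose(
            from_disk.data.to_numpy(), in_mem.data.to_numpy(), atol=1e-9
        )


class TestCorrelationMatrix:
    def _noise_table(self, n=200, cols=3, seed=14):
        rng = np.random.default_rng(seed)
        data = pd.DataFrame(
            rng.uniform(80, 100, (n, cols)),
            columns=pd.MultiIndex.from_tuples(
                [("gamma_global", 2.0, 2.0, float(k)) for k in range(cols)],
                names=["technique", "dd", "dta", "ldt"],
            ),
        )
        return da.AgreementTable(data, pd.Series(["clean"] * n))

    def test_self_pair_is_perfectly_correlated(self):
        table = self._noise_table()
        col = table.data.columns[0]
        report = da.correlation_matrix(table, family=[(col, col)])
        row = report.pairs.iloc[0]
        assert row.r2 == pytest.approx(1.0, abs=1e-12)
        assert row.correlated and row.significant_after_sidak

    def test_independent_noise_is_uncorrelated(self):
        table = self._noise_table()
        report = da.correlation_matrix(table)
        assert report.m == 3
        assert (report.pairs.r2 < 0.64).all()
        assert not report.pairs.correlated.any()

    def test_family_size_drives_sidak_level(self):
        table = self._noise_table(cols=4)
        report = da.correlation_matrix(table, alpha=0.05)
        assert report.m == 6
        assert report.corrected_alpha == pytest.approx(da.sidak_correct(0.05, 6), abs=1e-15)
        flagged = report.pairs.significant_after_sidak
        ok = report.pairs.p_value <= report.corrected_alpha
        assert (flagged == ok).all()

    def test_default_threshold_is_squared_pearson_08(self):
        table = self._noise_table()
        report = da.correlation_matrix(table)
        assert report.r2_threshold == 0.64
        assert report.r2_threshold == pytest.approx(0.8**2, abs=1e-12)

    def test_report_is_reproducible(self):
        table = self._noise_table()
        a = da.correlation_matrix(table)
        b = da.correlation_matrix(table)
        pd.testing.assert_frame_equal(a.pairs, b.pairs)

    def test_cross_technique_report_structure(self):
        """The cross-technique analysis at one criteria pair covers all ten
        unordered pairs of the five techniques."""
        pairs = da.cohort_pairs(n=6, errored_fraction=0.5, seed=19)
        table = da.batch_indices(pairs, da.TECHNIQUES, [(2.0, 2.0)], [10.0])
        cols = [(t, 2.0, 2.0, 10.0) for t in da.TECHNIQUES]
        import itertools

        family = list(itertools.combinations(cols, 2))
        report = da.correlation_matrix(table, family)
        assert len(report.pairs) == 10
        mat = report.r2_matrix()
        assert mat.shape == (5, 5)
        pd.testing.assert_frame_equal(mat, mat.T)
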