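import numpy as np
import pytest

import doseagree as da
from doseagree.errors import GeometryError, ValidationError


class TestGeneratePlan:
    def test_deterministic_in_spec_and_seed(self):
        a = da.generate_plan(da.PlanSpec(), 5)
        b = da.generate_plan(da.PlanSpec(), 5)
        np.testing.assert_array_equal(a.values, b.values)
        c = da.generate_plan(da.PlanSpec(), 6)
        assert not np.array_equal(a.values, c.values)

    def test_single_centered_lobe_is_rotation_symmetric(self):
        spec = da.PlanSpec(n_lobes=1, lobe_margin_mm=100.0, edge_jitter_mm=0.0)
        plan = da.generate_plan(spec, 9)
        np.testing.assert_allclose(plan.values, plan.values[::-1, ::-1], atol=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_all_four_isodose_bands_populated(self, seed):
        plan = da.generate_plan(da.PlanSpec(), seed)
        pct = 100.0 * plan.values / plan.max()
        for lo, hi in ((10, 20), (20, 50), (50, 90), (90, 100.0001)):
            assert np.any((pct >= lo) & (pct < hi)), f"band {lo}-{hi}% empty (seed {seed})"

    def test_relative_mode_normalizes(self):
        plan = da.generate_plan(da.PlanSpec(mode="relative"), 3)
        assert plan.mode == "relative"
        assert plan.max() == 100.0

    def test_grid_geometry(self):
        plan = da.generate_plan(da.PlanSpec(), 1)
        assert plan.shape == (201, 201)
        assert plan.spacing == (1.0, 1.0)
        assert plan.source is not None


class TestInjectErrors:
    def test_identity_model_returns_plan_unchanged(self):
        plan = da.generate_plan(da.PlanSpec(), 2)
        out = da.inject_errors(plan, da.IDENTITY_ERROR_MODEL, 99)
        np.testing.assert_array_equal(out.values, plan.values)

    def test_scaling_a_plateau_fails_tight_and_passes_loose_criterion(self):
        # 5% scale on a uniform 100% plateau: the global percent difference is
        # exactly 5 everywhere and no spatial search can reduce it
        ref = da.DoseGrid(np.full((11, 11), 100.0), (1, 1))
        scaled = da.inject_errors(ref, da.ErrorModel(scale_factor=1.05), 0)
        ev = da.sample_detector(scaled, 10.0)
        mask = da.EvaluationMask(np.ones(ev.shape, dtype=bool), 0.0)
        tight = da.gamma_map(ref, ev, da.CriteriaPair(3, 3, "global"), mask)
        loose = da.gamma_map(ref, ev, da.CriteriaPair(5, 3, "global"), mask)
        assert tight.agreement_index == 0.0
        np.testing.assert_allclose(loose.index_map, 1.0, atol=1e-12)
        assert loose.agreement_index == 100.0

    def test_pure_shift_within_dta_passes(self):
        plan = da.generate_plan(da.PlanSpec(), 8)
        shifted = da.inject_errors(plan, da.ErrorModel(shift_mm=(0.0, 2.0)), 0)
        meas = da.sample_detector(shifted, 10.0)
        mask = da.apply_ldt(plan, 10.0, on=meas)
        res = da.gamma_map(plan, meas, da.CriteriaPair(3, 3, "global"), mask)
        # the shifted analytic field re-sampled 2 mm away matches the
        # reference lattice exactly, so gamma <= 2/3 at every included point
        assert res.agreement_index == 100.0
        assert np.nanmax(res.index_map[mask.included]) <= 2.0 / 3.0 + 1e-9

    def test_shift_requires_analytic_source(self):
        grid = da.DoseGrid(np.ones((5, 5)), (1, 1))
        with pytest.raises(ValidationError):
            da.inject_errors(grid, da.ErrorModel(shift_mm=(1.0, 0.0)), 0)

    def test_shift_off_grid_is_geometry_error(self):
        plan = da.generate_plan(da.PlanSpec(), 4)
        with pytest.raises(GeometryError):
            da.inject_errors(plan, da.ErrorModel(shift_mm=(120.0, 0.0)), 0)

    def test_noise_is_seeded(self):
        plan = da.generate_plan(da.PlanSpec(), 3)
        model = da.ErrorModel(noise_sd_percent=0.5)
        a = da.inject_errors(plan, model, 7)
        b = da.inject_errors(plan, model, 7)
        c = da.inject_errors(plan, model, 8)
        np.testing.assert_array_equal(a.values, b.values)
        assert not np.array_equal(a.values, c.values)

    def test_blob_changes_dose_locally(self):
        plan = da.generate_plan(da.PlanSpec(), 3)
        model = da.ErrorModel(blob_errors=((100.0, 100.0, 10.0, 5.0),))
        out = da.inject_errors(plan, model, 0)
        center = out.values[100, 100] - plan.values[100, 100]
        assert center == pytest.approx(0.05 * plan.max(), rel=1e-9)
        far = abs(out.values[0, 0] - plan.values[0, 0])
        assert far < 1e-9 * plan.max()


class TestSampleDetector:
    def test_point_sampling_is_exact(self):
        plan = da.generate_plan(da.PlanSpec(), 6)
        meas = da.sample_detector(plan, 10.0)
        np.testing.assert_array_equal(meas.values, plan.values[::10, ::10])
        assert meas.spacing == (10.0, 10.0)

    def test_uniform_grid_downsamples_uniform(self):
        grid = da.DoseGrid(np.full((21, 21), 1.5), (1, 1))
        np.testing.assert_array_equal(da.sample_detector(grid, 10.0).values, 1.5)

    def test_sampled_extent_within_source_extent(self):
        plan = da.generate_plan(da.PlanSpec(), 6)
        meas = da.sample_detector(plan, 10.0)
        y0, y1, x0, x1 = plan.extent
        my0, my1, mx0, mx1 = meas.extent
        assert y0 <= my0 and my1 <= y1 and x0 <= mx0 and mx1 <= x1

    def test_non_integer_ratio_rejected(self):
        grid = da.DoseGrid(np.ones((10, 10)), (3.0, 3.0))
        with pytest.raises(ValidationError):
            da.sample_detector(grid, 10.0)


class TestCohort:
    def test_errored_count_rounds(self):
        pairs = da.cohort_pairs(n=50, errored_fraction=0.12, seed=1)
        assert sum(1 for p in pairs if p[3] == "errored") == 6
        assert len(pairs) == 50

    def test_clean_pairs_agree_exactly(self, default_cohort):
        clean = [(r, m) for _, r, m, lab in default_cohort if lab == "clean"][:3]
        for ref, meas in clean:
            mask = da.apply_ldt(ref, 10.0, on=meas)
            res = da.gamma_map(ref, meas, da.CriteriaPair(3, 3, "global"), mask)
            assert res.agreement_index == 100.0
            np.testing.assert_array_equal(res.index_map[mask.included], 0.0)

    def test_files_regenerate_bit_identically(self, tmp_path):
        out = tmp_path / "cohort"
        manifest = da.generate_cohort(4, 0.5, 3, out)
        reloaded = da.CohortManifest.from_tsv(out / "manifest.tsv")
        assert len(reloaded.records) == 4
        rec = reloaded.records[0]
        original = open(rec.ref_path, "rb").read(), open(rec.meas_path, "rb").read()
        da.regenerate_plan_files(reloaded, rec)
        again = open(rec.ref_path, "rb").read(), open(rec.meas_path, "rb").read()
        assert again == original

    def test_seeds_unique_per_plan(self, tmp_path):
        manifest = da.generate_cohort(12, 0.25, 9, tmp_path / "c")
        seeds = [r.seed for r in manifest.records]
        assert len(set(seeds)) == len(seeds)

    def test_relative_mode_pairs_are_normalized(self):
        pairs = da.cohort_pairs(n=3, errored_fraction=0.5, seed=2, mode="relative")
        for _, ref, meas, _ in pairs:
            assert ref.mode == meas.mode == "relative"
            assert ref.max() == 100.0 and meas.max() == 100.0

    def test_cohort_too_small_rejected(self):
        with pytest.raises(ValidationError):
            da.cohort_pairs(n=1, errored_fraction=0.0, seed=0)
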