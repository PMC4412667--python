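import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from setrcall.depth_normalization import (BaselineError, build_baseline,
                                          compute_pre_ratio, compute_ratio,
                                          compute_region_depth,
                                          leave_one_out_baseline,
                                          make_ratio_profile,
                                          normalize_by_baseline, smooth_depth)
from setrcall.io_formats import DepthProfile, TargetRegion, TargetSet


def _profiles(targets, td_rows):
    return [make_ratio_profile(DepthProfile(f"s{i}", td), targets)
            for i, td in enumerate(td_rows)]


class TestRegionDepth:
    def test_base_count_divided_by_length(self, small_targets):
        counts = np.full(10, 7_500.0)
        prof = compute_region_depth(counts, small_targets)
        np.testing.assert_allclose(prof.td, 50.0)

    def test_zero_bases_gives_zero_depth(self, small_targets):
        prof = compute_region_depth(np.zeros(10), small_targets)
        assert np.all(prof.td == 0)

    def test_mean_depth_dialect_passthrough(self, small_targets):
        vals = np.arange(10, dtype=float)
        prof = compute_region_depth(vals, small_targets, dialect="mean-depth")
        np.testing.assert_array_equal(prof.td, vals)


class TestSmoothing:
    def test_constant_vector_is_fixed_point(self, small_targets):
        prof = DepthProfile("s", np.full(10, 3.7))
        np.testing.assert_allclose(smooth_depth(prof, small_targets), 3.7)

    def test_window_is_self_plus_ten_downstream(self):
        ts = TargetSet([TargetRegion("chr1", k * 1000, k * 1000 + 100,
                                     f"r{k}", k) for k in range(12)])
        td = np.arange(1.0, 13.0)
        out = smooth_depth(DepthProfile("s", td), ts, n=10)
        assert out[0] == pytest.approx(6.0)  # mean of 1..11

    def test_window_truncates_at_chromosome_end(self, small_targets):
        td = np.arange(1.0, 11.0)
        out = smooth_depth(DepthProfile("s", td), small_targets, n=10)
        assert out[-1] == pytest.approx(td[-1])      # window of one
        assert out[-2] == pytest.approx(np.mean(td[-2:]))

    def test_windows_never_cross_chromosomes(self, two_chrom_targets):
        td = np.concatenate([np.full(12, 1.0), np.full(8, 5.0)])
        out = smooth_depth(DepthProfile("s", td), two_chrom_targets, n=10)
        np.testing.assert_allclose(out[:12], 1.0)
        np.testing.assert_allclose(out[12:], 5.0)

    def test_mean_preserved_exactly_for_constant_chromosomes(self, two_chrom_targets):
        td = np.concatenate([np.full(12, 2.0), np.full(8, 8.0)])
        out = smooth_depth(DepthProfile("s", td), two_chrom_targets)
        assert np.mean(out[:12]) == pytest.approx(2.0)
        assert np.mean(out[12:]) == pytest.approx(8.0)


class TestRatios:
    def test_pre_ratio_examples(self, small_targets):
        assert np.allclose(compute_pre_ratio(DepthProfile("s", np.full(10, 9.0))), 1.0)
        pre = compute_pre_ratio(DepthProfile("s", np.array([10.0, 30.0])))
        np.testing.assert_allclose(pre, [0.5, 1.5])

    def test_empty_library_rejected(self):
        with pytest.raises(ValueError, match="empty library"):
            compute_pre_ratio(DepthProfile("s", np.zeros(5)))

    def test_ratio_divisor_is_autosomal_only(self):
        regions = [TargetRegion("chr1", k * 1000, k * 1000 + 100, f"a{k}", k)
                   for k in range(4)]
        regions += [TargetRegion("chrX", k * 1000, k * 1000 + 100, f"x{k}", k + 4)
                    for k in range(4)]
        ts = TargetSet(regions)
        td_m = np.array([2.0] * 4 + [1.0] * 4)
        r, denom = compute_ratio(td_m, ts)
        assert denom == pytest.approx(2.0)          # autosomes only
        np.testing.assert_allclose(r[:4], 1.0)
        np.testing.assert_allclose(r[4:], 0.5)      # male-like chrX

    def test_zero_autosomal_mean_rejected(self, small_targets):
        with pytest.raises(ValueError):
            compute_ratio(np.zeros(10), small_targets)


class TestBaseline:
    def test_identical_samples_reproduce_themselves(self, small_targets, rng):
        td = rng.uniform(10, 50, 10)
        profs = _profiles(small_targets, [td.copy() for _ in range(9)])
        panel = build_baseline(profs, min_samples=8)
        np.testing.assert_allclose(panel.median_r, profs[0].r)

    def test_median_of_three(self, small_targets):
        profs = _profiles(small_targets,
                          [np.full(10, v) for v in (0.8, 1.0, 1.2)])
        panel = build_baseline(profs, min_samples=3)
        # constant profiles all normalize to r = 1; use raw median instead
        r_stack = np.vstack([p.r for p in profs])
        assert np.median(r_stack[:, 0]) == pytest.approx(1.0)
        assert panel.n_samples == 3

    def test_minimum_sample_rule_enforced(self, small_targets):
        profs = _profiles(small_targets, [np.full(10, 1.0)] * 5)
        with pytest.raises(BaselineError, match="8"):
            build_baseline(profs)

    def test_median_robust_to_one_deletion_carrier(self, small_targets, rng):
        base = rng.uniform(20, 40, 10)
        rows = [base * rng.normal(1, 0.01, 10) for _ in range(9)]
        aberrant = rows[0].copy()
        aberrant[4] *= 0.5                       # deletion at target 4
        rows_with = [aberrant] + rows[1:]
        p_clean = build_baseline(_profiles(small_targets, rows), min_samples=8)
        p_dirty = build_baseline(_profiles(small_targets, rows_with), min_samples=8)
        assert p_dirty.median_r[4] == pytest.approx(p_clean.median_r[4], rel=0.02)

    def test_leave_one_out_excludes_test_sample(self, small_targets, rng):
        rows = [rng.uniform(10, 50, 10) for _ in range(9)]
        profs = _profiles(small_targets, rows)
        loo = leave_one_out_baseline(profs, 0, min_samples=8)
        full = build_baseline(profs, min_samples=8)
        assert loo.n_samples == 8
        assert not np.allclose(loo.median_r, full.median_r)


class TestNormalization:
    def test_panel_median_sample_maps_to_one(self, small_targets, rng):
        td = rng.uniform(10, 50, 10)
        profs = _profiles(small_targets, [td.copy() for _ in range(9)])
        panel = build_baseline(profs, min_samples=8)
        out = normalize_by_baseline(profs[0], panel)
        np.testing.assert_allclose(out.r_m, 1.0)

    def test_masked_targets_propagate_as_nan(self, small_targets, rng):
        td = rng.uniform(10, 50, 10)
        profs = _profiles(small_targets, [td.copy() for _ in range(9)])
        panel = build_baseline(profs, min_samples=8)
        panel.mask[3] = True
        out = normalize_by_baseline(profs[0], panel)
        assert np.isnan(out.r_m[3])
        assert np.isfinite(np.delete(out.r_m, 3)).all()

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(min_value=0.01, max_value=100.0))
    def test_r_m_invariant_to_library_size(self, scale):
        ts = TargetSet([TargetRegion("chr1", k * 1000, k * 1000 + 100,
                                     f"r{k}", k) for k in range(20)])
        rng = np.random.default_rng(42)
        rows = [rng.uniform(10, 50, 20) for _ in range(9)]
        profs = _profiles(ts, rows)
        panel = build_baseline(profs, min_samples=8)
        a = normalize_by_baseline(_profiles(ts, [rows[0]])[0], panel)
        b = normalize_by_baseline(_profiles(ts, [rows[0] * scale])[0], panel)
        np.testing.assert_allclose(a.r_m, b.r_m, rtol=1e-9)


def test_normalization_shrinks_dispersion_on_null_panel():
    """Dividing by the panel median cancels per-probe capture efficiency:
    SD(R_m) < SD(preR) and mean(R_m) stays near 1 for every sample."""
    import setrcall.synthetic_data as syn

    ds = syn.null_scenario(123, n_samples=10, chrom_length_bp=10_000_000)
    profs = _profiles(ds.targets, [ds.depths[s].td for s in ds.sample_ids])
    panel = build_baseline(profs, min_samples=8)
    for p in profs:
        out = normalize_by_baseline(p, panel)
        ok = np.isfinite(out.r_m)
        assert np.std(out.r_m[ok]) < np.std(out.pre_r[ok])
        assert 0.95 <= np.mean(out.r_m[ok]) <= 1.05
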