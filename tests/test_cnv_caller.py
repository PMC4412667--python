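import numpy as np
import pytest
from scipy import stats

from setrcall.cnv_caller import (CnvParams, assign_copy_number, call_cnvs,
                                 format_karyotype, infer_sex,
                                 merge_marked_runs, probe_level_ttest,
                                 probe_tests, region_level_ttest,
                                 seed_pseudo_signals, SexAssignment, CnvCall)
from setrcall.depth_normalization import (BaselinePanel, make_ratio_profile,
                                          normalize_by_baseline)
from setrcall.io_formats import DepthProfile, TargetRegion, TargetSet


# ---------------------------------------------------------------------------
# Probe-level t
# ---------------------------------------------------------------------------

class TestProbeTtest:
    def test_matches_textbook_formula_on_random_fixtures(self, rng):
        """t = (x - mean) / sqrt(S^2 (1 + 1/n)) with df n-1, two-sided p."""
        for _ in range(1000):
            n = int(rng.integers(5, 30))
            panel = rng.normal(1, rng.uniform(0.05, 0.5), n)
            x = float(rng.normal(1, 0.5))
            res = probe_level_ttest(x, panel)
            mean = sum(panel) / n
            s2 = sum((v - mean) ** 2 for v in panel) / (n - 1)
            t_exp = (x - mean) / (s2 * (1 + 1 / n)) ** 0.5
            p_exp = 2 * (1 - stats.t.cdf(abs(t_exp), n - 1))
            assert res.t_score == pytest.approx(t_exp, abs=1e-10)
            assert res.p_value == pytest.approx(p_exp, abs=1e-10)

    def test_equal_to_panel_mean_gives_p_one(self):
        panel = np.array([0.9, 1.0, 1.1, 1.0, 1.0])
        res = probe_level_ttest(float(np.mean(panel)), panel)
        assert res.t_score == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_two_sided_symmetry(self, rng):
        panel = rng.normal(1, 0.1, 10)
        x = 0.5
        mirrored = 2 * float(np.mean(panel)) - x
        assert probe_level_ttest(x, panel).p_value == pytest.approx(
            probe_level_ttest(mirrored, panel).p_value, abs=1e-12)

    def test_strong_deviation_is_significant(self, rng):
        panel = 1.0 + rng.normal(0, 0.01, 10)
        res = probe_level_ttest(0.5, panel)
        assert abs(res.t_score) > 10 and res.p_value < 0.05

    def test_zero_variance_panel_masked(self):
        res = probe_level_ttest(0.5, np.ones(10))
        assert np.isnan(res.p_value)

    def test_vectorized_agrees_with_scalar(self, rng):
        panel = rng.normal(1, 0.1, (8, 50))
        test = rng.normal(1, 0.2, 50)
        out = probe_tests(test, panel)
        for i in (0, 17, 49):
            ref = probe_level_ttest(test[i], panel[:, i])
            assert out["t"][i] == pytest.approx(ref.t_score, abs=1e-12)
            assert out["p"][i] == pytest.approx(ref.p_value, abs=1e-12)


# ---------------------------------------------------------------------------
# Seeding and merging
# ---------------------------------------------------------------------------

class TestSeeding:
    def _chrom(self, n):
        return np.array(["chr1"] * n, dtype=object)

    def test_three_under_first_threshold_fourth_under_second(self):
        t = np.full(4, -3.0)
        p = np.array([0.01, 0.02, 0.03, 0.15])
        marks = seed_pseudo_signals(t, p, self._chrom(4))
        assert list(marks) == ["-"] * 4

    def test_fourth_pvalue_above_second_threshold_blocks(self):
        t = np.full(4, -3.0)
        p = np.array([0.01, 0.02, 0.03, 0.25])
        assert list(seed_pseudo_signals(t, p, self._chrom(4))) == [""] * 4

    def test_mixed_signs_block(self):
        t = np.array([-3.0, -3.0, 3.0, -3.0])
        p = np.full(4, 0.01)
        assert list(seed_pseudo_signals(t, p, self._chrom(4))) == [""] * 4

    def test_overlapping_windows_accumulate_marks(self):
        t = np.full(6, 2.0)
        p = np.array([0.01, 0.01, 0.01, 0.01, 0.01, 0.01])
        assert list(seed_pseudo_signals(t, p, self._chrom(6))) == ["+"] * 6

    def test_windows_never_span_chromosomes(self):
        t = np.full(4, -3.0)
        p = np.full(4, 0.01)
        chrom = np.array(["chr1", "chr1", "chr2", "chr2"], dtype=object)
        assert list(seed_pseudo_signals(t, p, chrom)) == [""] * 4


class TestMerging:
    def _marks(self, spec):
        return np.array(list(spec), dtype="<U1"), \
            np.array(["chr1"] * len(spec), dtype=object)

    def test_small_gap_merges_including_gap_probes(self):
        marks, chrom = self._marks("----" + "." * 3 + "----")
        marks[marks == "."] = ""
        runs = merge_marked_runs(marks, chrom, max_gap=5)
        assert runs == [(0, 11, "-")]

    def test_six_probe_gap_does_not_merge(self):
        marks, chrom = self._marks("----" + "." * 6 + "----")
        marks[marks == "."] = ""
        runs = merge_marked_runs(marks, chrom, max_gap=5)
        assert runs == [(0, 4, "-"), (10, 14, "-")]

    def test_opposite_signs_never_merge(self):
        marks, chrom = self._marks("----++++")
        runs = merge_marked_runs(marks, chrom, max_gap=5)
        assert runs == [(0, 4, "-"), (4, 8, "+")]

    def test_runs_split_at_chromosome_boundary(self):
        marks = np.array(["-"] * 8, dtype="<U1")
        chrom = np.array(["chr1"] * 4 + ["chr2"] * 4, dtype=object)
        runs = merge_marked_runs(marks, chrom, max_gap=5)
        assert runs == [(0, 4, "-"), (4, 8, "-")]


# ---------------------------------------------------------------------------
# Region-level t and CN
# ---------------------------------------------------------------------------

class TestRegionTtest:
    def test_matches_one_sample_oracle_on_random_fixtures(self, rng):
        for _ in range(1000):
            m = int(rng.integers(4, 60))
            z = rng.normal(rng.uniform(-0.5, 0.5), rng.uniform(0.05, 0.4), m)
            t, p = region_level_ttest(z)
            t_ref, p_ref = stats.ttest_1samp(z, 0.0)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)

    def test_strong_negative_interval(self):
        z = np.array([-0.5, -0.5, -0.48, -0.52])
        t, p = region_level_ttest(z)
        assert t < -50 and p < 0.01

    def test_symmetric_interval_not_significant(self, rng):
        z = np.concatenate([rng.normal(0.3, 0.01, 5), rng.normal(-0.3, 0.01, 5)])
        _, p = region_level_ttest(z)
        assert p > 0.5

    def test_degenerate_zero_dispersion_flagged(self):
        t, p = region_level_ttest(np.zeros(6))
        assert p == np.finfo(float).tiny


class TestCopyNumber:
    @pytest.mark.parametrize("ratio,cn", [
        (1.0, 2),
        (1.7485, 3),   # continuous CN estimate 3.497 rounds down to 3
        (0.5, 1),
        (0.05, 0),
        (0.75, 2),     # half-up tie-break
        (0.0, 0),
    ])
    def test_rounding_rule(self, ratio, cn):
        assert assign_copy_number(ratio) == cn

    def test_never_negative(self):
        assert assign_copy_number(0.0) == 0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            assign_copy_number(float("nan"))


# ---------------------------------------------------------------------------
# Sex and karyotype
# ---------------------------------------------------------------------------

def _sex_grid():
    regions = []
    i = 0
    for chrom, n in [("chr1", 60), ("chrX", 30), ("chrY", 10)]:
        for k in range(n):
            regions.append(TargetRegion(chrom, k * 10_000, k * 10_000 + 150,
                                        f"{chrom}_{k}", i))
            i += 1
    return TargetSet(regions)


class TestSexInference:
    def _profile(self, ts, x_cn, y_cn, rng):
        ch = ts.chrom_of()
        cn = np.full(len(ts), 2.0)
        cn[ch == "chrX"] = x_cn
        cn[ch == "chrY"] = y_cn
        td = rng.poisson(60 * cn / 2).astype(float)
        return make_ratio_profile(DepthProfile("s", td), ts)

    def test_simulated_female(self, rng):
        ts = _sex_grid()
        assert infer_sex(self._profile(ts, 2, 0, rng), ts).sex == "XX"

    def test_simulated_male(self, rng):
        ts = _sex_grid()
        assert infer_sex(self._profile(ts, 1, 1, rng), ts).sex == "XY"

    def test_ambiguous_band_flagged(self, rng):
        ts = _sex_grid()
        prof = self._profile(ts, 2, 0, rng)
        prof.r[ts.chrom_of() == "chrX"] = 0.8
        assert infer_sex(prof, ts).sex == "other"


class TestKaryotype:
    @pytest.fixture
    def cytobands(self):
        import pandas as pd
        from setrcall.io_formats import CytobandTable
        return CytobandTable(pd.DataFrame(
            [("chr5", 0, 20_000_000, "p14", "gneg"),
             ("chr5", 20_000_000, 46_000_000, "p13", "gpos50")],
            columns=CytobandTable.COLS))

    def test_normal_male(self, cytobands):
        sex = SexAssignment("s", "XY", 0.5, 0.5)
        assert format_karyotype(sex, [], cytobands) == "46,XY"

    def test_segmental_deletion_with_band(self, cytobands):
        sex = SexAssignment("s", "XY", 0.5, 0.5)
        call = CnvCall("s", "chr5", 5_000_000, 15_000_000, 1000, 0.5,
                       -10.0, 1e-9, 1, "loss")
        assert format_karyotype(sex, [call], cytobands) == "46,XY,del(5)(p14)"

    def test_triple_x_plus_trisomy_18(self, cytobands):
        sex = SexAssignment("s", "XX", 1.0, 0.0)
        t18 = CnvCall("s", "chr18", 0, 60_000_000, 6000, 1.5, 10.0, 1e-9, 3,
                      "gain", is_aneuploidy=True)
        xxx = CnvCall("s", "chrX", 0, 150_000_000, 1500, 1.5, 10.0, 1e-9, 3,
                      "gain", is_aneuploidy=True)
        assert format_karyotype(sex, [t18, xxx], cytobands) == "48,XXX,+18"


# ---------------------------------------------------------------------------
# Full chain
# ---------------------------------------------------------------------------

def _panel_with_implant(rng, n_probes=400, n_samples=9, depth=30.0,
                        event=(150, 250), cn=1, split_chrom=False):
    if split_chrom:
        # chr2 is a small fraction of the grid, as a real chromosome is of
        # a genome, so its aneuploidy barely moves the autosomal mean
        n1 = split_chrom if isinstance(split_chrom, int) else n_probes // 2
        regions = [TargetRegion("chr1", k * 10_000, k * 10_000 + 150,
                                f"chr1_{k}", k) for k in range(n1)]
        regions += [TargetRegion("chr2", k * 10_000, k * 10_000 + 150,
                                 f"chr2_{k}", n1 + k)
                    for k in range(n_probes - n1)]
        ts = TargetSet(regions)
    else:
        ts = TargetSet([TargetRegion("chr1", k * 10_000, k * 10_000 + 150,
                                     f"chr1_{k}", k) for k in range(n_probes)])
    eff = rng.lognormal(0, 0.4, n_probes)
    rows = [rng.poisson(depth * eff).astype(float) for _ in range(n_samples)]
    cn_vec = np.full(n_probes, 2.0)
    if event is not None:
        cn_vec[event[0]:event[1]] = cn
    rows[0] = rng.poisson(depth * eff * cn_vec / 2).astype(float)
    profs = [make_ratio_profile(DepthProfile(f"s{i}", td), ts)
             for i, td in enumerate(rows)]
    R = np.vstack([p.r for p in profs])
    PRE = np.vstack([p.pre_r for p in profs])
    med, medp = np.median(R[1:], axis=0), np.median(PRE[1:], axis=0)
    panel = BaselinePanel(med, medp, n_samples - 1, [])
    prof = normalize_by_baseline(profs[0], panel)
    return ts, prof, R[1:] / med, PRE[1:] / medp


class TestCallCnvs:
    def test_implanted_deletion_recovered_with_tight_boundaries(self, rng):
        ts, prof, panel_rm, panel_raw = _panel_with_implant(rng)
        params = CnvParams(min_probes=10, min_size_bp=0)
        calls = call_cnvs(prof, panel_rm, ts, params, panel_raw=panel_raw)
        assert len(calls) == 1
        c = calls[0]
        assert c.cn == 1 and c.direction == "loss"
        assert abs(c.probe_span[0] - 150) <= 2
        assert abs(c.probe_span[1] - 250) <= 2

    def test_panel_median_sample_yields_zero_calls(self, rng):
        ts, prof, panel_rm, panel_raw = _panel_with_implant(rng, event=None)
        params = CnvParams(min_probes=10, min_size_bp=0)
        assert call_cnvs(prof, panel_rm, ts, params, panel_raw=panel_raw) == []

    def test_whole_chromosome_gain_reported_as_aneuploidy(self, rng):
        # trisomy of chr2 (probes 360..400); chr1 anchors the autosomal mean
        ts, prof, panel_rm, panel_raw = _panel_with_implant(
            rng, event=(360, 400), cn=3, split_chrom=360)
        params = CnvParams(min_probes=10, min_size_bp=0)
        calls = call_cnvs(prof, panel_rm, ts, params, panel_raw=panel_raw)
        assert len(calls) >= 1
        assert any(c.is_aneuploidy and c.cn == 3 for c in calls)


def test_probe_pvalues_approximately_uniform_on_null(rng):
    """Two-sided probe-level p on null panels should be ~Uniform(0,1)."""
    n_panel, n_probes = 12, 5000
    panel = rng.normal(1, 0.1, (n_panel, n_probes))
    test = rng.normal(1, 0.1, n_probes)
    out = probe_tests(test, panel)
    stat, p = stats.kstest(out["p"], "uniform")
    assert p > 0.01
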