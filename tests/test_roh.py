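"""ROH detection against a brute-force window oracle, F_ROH arithmetic,
length classes, per-chromosome coverage and SNP-in-ROH incidence."""

import numpy as np
import pytest

from caprapop.io import MISSING
from caprapop.roh import (FrohRecord, ROHParams, ROHSegment,
                          autosome_coverage_bp, avg_pct_roh_per_chromosome,
                          detect_roh, froh, roh_class_spectrum,
                          snp_in_roh_incidence)
from conftest import make_dataset

MB = 1_000_000


def brute_force_eligible(genos, params):
    """Oracle: direct per-SNP hit-rate computation over all windows."""
    m = len(genos)
    w = params.window_snps
    elig = np.zeros(m, dtype=bool)
    win_ok = []
    for s in range(m - w + 1):
        win = genos[s:s + w]
        win_ok.append(sum(g == 1 for g in win) <= params.window_max_het
                      and sum(g == MISSING for g in win) <= params.window_max_missing)
    for j in range(m):
        overlapping = [win_ok[s] for s in range(max(0, j - w + 1),
                                                min(j, m - w) + 1)]
        if overlapping:
            elig[j] = sum(overlapping) / len(overlapping) >= params.window_hit_threshold
    return elig


class TestDetect:
    def make_single_sample(self, genos, spacing=40_000):
        genos = np.asarray(genos, dtype=np.int8)[None, :]
        bp = (np.arange(genos.shape[1]) + 1) * spacing
        return make_dataset(genos, bp=bp)

    def test_fully_heterozygous_no_segments(self):
        ds = self.make_single_sample([1] * 100)
        assert detect_roh(ds) == []

    def test_constructed_stretch_single_segment(self):
        # 60 homozygous SNPs spanning 2.36 Mb at uniform 40-kb spacing with
        # one interior het, flanked by heterozygous background
        genos = [1] * 20 + [0] * 30 + [1] + [2] * 29 + [1] * 20
        ds = self.make_single_sample(genos)
        segs = detect_roh(ds)
        assert len(segs) == 1
        seg = segs[0]
        bp = ds.bp_positions
        assert seg.start_bp == bp[20]
        assert seg.end_bp == bp[79]
        assert seg.n_snps == 60

    def test_matches_brute_force_eligibility(self):
        rng = np.random.default_rng(5)
        params = ROHParams()
        genos = rng.choice([0, 1, 2, MISSING], size=300,
                           p=[0.45, 0.08, 0.45, 0.02]).astype(np.int8)
        from caprapop.roh import _eligible_snps
        got = _eligible_snps(genos == 1, genos == MISSING, params)
        want = brute_force_eligible(list(genos), params)
        np.testing.assert_array_equal(got, want)

    def test_unsorted_markers_rejected(self):
        ds = make_dataset([[0, 0]], bp=[2000, 1000])
        with pytest.raises(ValueError, match="sorted"):
            detect_roh(ds)

    def test_short_stretch_filtered_by_min_snps(self):
        genos = [1] * 20 + [0] * 10 + [1] * 20   # only 10 hom SNPs
        ds = self.make_single_sample(genos, spacing=200_000)
        assert detect_roh(ds) == []

    def test_gap_splits_run(self):
        # two 30-SNP homozygous blocks separated by a 5-Mb gap
        genos = np.zeros(60, dtype=np.int8)
        bp = np.concatenate([np.arange(1, 31) * 40_000,
                             5 * MB + np.arange(31, 61) * 40_000])
        ds = make_dataset(genos[None, :], bp=bp)
        segs = detect_roh(ds)
        assert len(segs) == 2
        assert all(s.n_snps == 30 for s in segs)


class TestFroh:
    def fake_ds(self, n_samples=2):
        # one chromosome spanning 0 to 2500 Mb via two markers
        d = np.zeros((n_samples, 2), dtype=np.int8)
        return make_dataset(d, bp=[1, 2500 * MB + 1])

    def test_no_segments_all_zero(self):
        recs = froh([], self.fake_ds())
        assert all(r.froh_total == 0 for r in recs)

    def test_hand_arithmetic_and_binning(self):
        ds = self.fake_ds()
        segs = [ROHSegment("s0", "1", 100 * MB, 150 * MB, 500)]
        rec = froh(segs, ds)[0]
        assert rec.froh_total == pytest.approx(0.02)
        assert rec.froh_gt20mb == pytest.approx(0.02)
        assert rec.froh_lt10mb == 0 and rec.froh_10_20mb == 0

    def test_bins_sum_to_total(self):
        rng = np.random.default_rng(6)
        segs = [ROHSegment("s0", "1", int(a), int(a + l), 100)
                for a, l in zip(rng.integers(0, 2000 * MB, 20),
                                rng.integers(1 * MB, 40 * MB, 20))]
        rec = froh(segs, self.fake_ds())[0]
        assert rec.froh_lt10mb + rec.froh_10_20mb + rec.froh_gt20mb == \
            pytest.approx(rec.froh_total, abs=1e-15)

    def test_empty_map_rejected(self):
        ds = self.fake_ds()
        ds.markers = []
        with pytest.raises(Exception):
            autosome_coverage_bp(make_dataset(np.zeros((1, 0), dtype=np.int8),
                                              bp=[], chrom=[]))


class TestSpectrumAndSummaries:
    def test_all_short_segments_first_class(self):
        segs = [ROHSegment("s0", "1", 0, 2 * MB, 50)] * 4
        spec = roh_class_spectrum(segs)
        assert spec.loc[0, "count"] == 4
        assert spec.loc[0, "freq"] == pytest.approx(1.0)

    def test_one_segment_per_class_boundaries(self):
        lengths = [2, 4, 8, 15, 25, 40]
        segs = [ROHSegment("s0", "1", 0, l * MB, 10) for l in lengths]
        spec = roh_class_spectrum(segs)
        assert list(spec["count"]) == [1] * 6

    def test_avg_pct_formula(self):
        # two animals with 10 and 20 Mb of ROH on a 100-Mb chromosome
        ds = make_dataset(np.zeros((3, 2), dtype=np.int8), bp=[1, 100 * MB + 1])
        segs = [ROHSegment("s0", "1", 0, 10 * MB, 10),
                ROHSegment("s1", "1", 0, 20 * MB, 10)]
        tab = avg_pct_roh_per_chromosome(segs, ds)
        assert tab.loc[0, "avg_pct"] == pytest.approx(15.0)

    def test_no_roh_chromosome_flagged_zero(self):
        ds = make_dataset(np.zeros((2, 2), dtype=np.int8), bp=[1, 100 * MB])
        tab = avg_pct_roh_per_chromosome([], ds)
        assert tab.loc[0, "avg_pct"] == 0.0
        assert bool(tab.loc[0, "no_roh"])

    def test_full_chromosome_single_animal_100pct(self):
        ds = make_dataset(np.zeros((1, 2), dtype=np.int8), bp=[1, 100 * MB + 1])
        segs = [ROHSegment("s0", "1", 1, 100 * MB + 1, 2)]
        tab = avg_pct_roh_per_chromosome(segs, ds)
        assert tab.loc[0, "avg_pct"] == pytest.approx(100.0)


class TestIncidence:
    def test_no_segments_zero(self):
        ds = make_dataset(np.zeros((5, 4), dtype=np.int8))
        assert (snp_in_roh_incidence([], ds) == 0).all()

    def test_one_in_ten_gives_ten_percent(self):
        ds = make_dataset(np.zeros((10, 4), dtype=np.int8),
                          bp=[1000, 2000, 3000, 4000])
        segs = [ROHSegment("s0", "1", 1500, 3500, 2)]
        inc = snp_in_roh_incidence(segs, ds)
        np.testing.assert_allclose(inc, [0, 10, 10, 0])

    def test_bounded_and_steps_at_boundaries(self):
        ds = make_dataset(np.zeros((4, 6), dtype=np.int8),
                          bp=[1, 10, 20, 30, 40, 50])
        segs = [ROHSegment(f"s{i}", "1", 5, 45, 4) for i in range(4)]
        inc = snp_in_roh_incidence(segs, ds)
        assert inc.max() <= 100
        np.testing.assert_allclose(inc, [0, 100, 100, 100, 100, 0])
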