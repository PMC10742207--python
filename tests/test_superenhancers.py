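"""Stitching, region scoring, rank-ordering SE calls, and score comparisons."""

import numpy as np
import pytest

from fusebind.intervals import GenomicInterval
from fusebind.simulate import SimulationConfig, gen_coverage
from fusebind.superenhancers import (
    CoverageTrack,
    StitchedRegion,
    call_superenhancers,
    compare_site_classes,
    read_bedgraph,
    score_region,
    score_regions,
    se_binding_overlap,
    stitch_peaks,
)
from fusebind.intervals import BedParseError


def region(chrom, start, end, signal=0.0):
    return StitchedRegion(
        interval=GenomicInterval(chrom, start, end),
        constituents=(GenomicInterval(chrom, start, end),),
        net_signal=signal,
    )


class TestBedgraph:
    def test_basic_step(self, tmp_path):
        p = tmp_path / "x.bg"
        p.write_text("chr1\t0\t100\t2.0\n")
        track = read_bedgraph(p)
        assert track.total_signal("chr1", 0, 100) == 200.0

    def test_unsorted_input_sorted(self, tmp_path):
        p = tmp_path / "x.bg"
        p.write_text("chr1\t100\t200\t1\nchr1\t0\t100\t2\n")
        track = read_bedgraph(p)
        assert track.steps["chr1"][0][0] == 0

    def test_overlapping_steps_error(self, tmp_path):
        p = tmp_path / "x.bg"
        p.write_text("chr1\t0\t100\t1\nchr1\t50\t150\t1\n")
        with pytest.raises(BedParseError, match="overlap"):
            read_bedgraph(p)


class TestStitching:
    def test_gap_within_distance_merges(self):
        peaks = [GenomicInterval("chr1", 0, 1_000),
                 GenomicInterval("chr1", 13_000, 13_400)]
        (merged,) = stitch_peaks(peaks)  # gap 12,000 <= 12,500
        assert (merged.interval.start, merged.interval.end) == (0, 13_400)
        assert len(merged.constituents) == 2

    def test_gap_beyond_distance_splits(self):
        peaks = [GenomicInterval("chr1", 0, 1_000),
                 GenomicInterval("chr1", 14_000, 14_400)]
        assert len(stitch_peaks(peaks)) == 2  # gap 13,000 > 12,500

    def test_gap_exactly_at_distance_merges(self):
        peaks = [GenomicInterval("chr1", 0, 1_000),
                 GenomicInterval("chr1", 13_500, 13_900)]
        assert len(stitch_peaks(peaks)) == 1  # inclusive boundary

    def test_single_peak_identity(self):
        (r,) = stitch_peaks([GenomicInterval("chr1", 10, 20)])
        assert (r.interval.start, r.interval.end) == (10, 20)

    def test_idempotent(self, rng):
        starts = np.sort(rng.integers(0, 1_000_000, size=200))
        peaks = [GenomicInterval("chr1", int(s), int(s) + 500) for s in starts]
        once = stitch_peaks(peaks)
        twice = stitch_peaks([r.interval for r in once])
        assert [r.interval for r in once] == [r.interval for r in twice]

    def test_span_is_hull_of_constituents(self, rng):
        starts = np.sort(rng.integers(0, 500_000, size=100))
        peaks = [GenomicInterval("chr1", int(s), int(s) + 300) for s in starts]
        for r in stitch_peaks(peaks):
            assert r.interval.start == min(p.start for p in r.constituents)
            assert r.interval.end == max(p.end for p in r.constituents)

    def test_tss_exclusion_drops_contained_peaks(self):
        peaks = [GenomicInterval("chr1", 1_000, 1_200),
                 GenomicInterval("chr1", 50_000, 50_200)]
        exclusion = [GenomicInterval("chr1", 500, 2_000)]
        regions = stitch_peaks(peaks, tss_exclusion=exclusion)
        assert [r.interval.start for r in regions] == [50_000]


class TestScoring:
    def test_uniform_depth_arithmetic(self):
        chip = CoverageTrack.from_records([("chr1", 0, 1_000, 3.0)])
        inp = CoverageTrack.from_records([("chr1", 0, 1_000, 1.0)])
        r = score_region(region("chr1", 0, 1_000), chip, inp)
        assert r.net_signal == 2_000.0

    def test_input_excess_floored_at_zero(self):
        chip = CoverageTrack.from_records([("chr1", 0, 1_000, 1.0)])
        inp = CoverageTrack.from_records([("chr1", 0, 1_000, 5.0)])
        assert score_region(region("chr1", 0, 1_000), chip, inp).net_signal == 0.0

    def test_matches_per_base_oracle(self, rng):
        for _ in range(20):
            edges = np.sort(rng.choice(np.arange(1, 5_000), size=30, replace=False))
            bounds = [0, *edges.tolist(), 5_000]
            chip_steps, inp_steps = [], []
            chip_arr = np.zeros(5_000)
            inp_arr = np.zeros(5_000)
            for lo, hi in zip(bounds, bounds[1:]):
                d1, d2 = rng.uniform(0, 5, size=2)
                if rng.random() < 0.8:
                    chip_steps.append(("chr1", lo, hi, d1))
                    chip_arr[lo:hi] = d1
                if rng.random() < 0.8:
                    inp_steps.append(("chr1", lo, hi, d2))
                    inp_arr[lo:hi] = d2
            chip = CoverageTrack.from_records(chip_steps)
            inp = CoverageTrack.from_records(inp_steps)
            lo = int(rng.integers(0, 2_000))
            hi = int(rng.integers(lo + 1, 5_000))
            r = score_region(region("chr1", lo, hi), chip, inp)
            expected = max(chip_arr[lo:hi].sum() - inp_arr[lo:hi].sum(), 0.0)
            assert r.net_signal == pytest.approx(expected)


class TestCallSuperenhancers:
    def test_single_outlier_is_super(self):
        regions = [region("chr1", i * 10_000, i * 10_000 + 100, s)
                   for i, s in enumerate([1.0, 2.0, 3.0, 100.0])]
        called = call_superenhancers(regions)
        assert [r.is_super for r in called] == [False, False, False, True]
        assert sorted(r.rank for r in called) == [1, 2, 3, 4]

    def test_degenerate_equal_signals(self):
        regions = [region("chr1", i * 10_000, i * 10_000 + 100, 5.0)
                   for i in range(4)]
        with pytest.warns(UserWarning):
            called = call_superenhancers(regions)
        assert not any(r.is_super for r in called)

    def test_scale_invariance(self, rng):
        signals = rng.exponential(1.0, size=100)
        signals[:5] += 50
        regions = [region("chr1", i * 10_000, i * 10_000 + 100, float(s))
                   for i, s in enumerate(signals)]
        base = {r.interval.start for r in call_superenhancers(regions) if r.is_super}
        scaled = [
            StitchedRegion(r.interval, r.constituents, net_signal=r.net_signal * 37.5)
            for r in regions
        ]
        assert {r.interval.start for r in call_superenhancers(scaled)
                if r.is_super} == base

    def test_cutoff_equals_exhaustive_scan(self, rng):
        signals = np.concatenate([rng.exponential(1.0, 200), rng.normal(60, 4, 10)])
        regions = [region("chr1", i * 10_000, i * 10_000 + 100, float(max(s, 0)))
                   for i, s in enumerate(signals)]
        called = call_superenhancers(regions)
        # exhaustive oracle over every candidate tangent point
        s = np.sort([r.net_signal for r in regions])
        x = np.arange(len(s)) / (len(s) - 1)
        y = (s - s.min()) / (s.max() - s.min())
        best = max(range(len(s)), key=lambda i: (x[i] - y[i], i))
        cutoff = s[best]
        expected = {r.interval.start for r in regions if r.net_signal > cutoff}
        assert {r.interval.start for r in called if r.is_super} == expected

    def test_planted_supers_all_recovered(self):
        config = SimulationConfig(seed=11)
        peaks, chip, inp, truth = gen_coverage(config)
        regions = score_regions(stitch_peaks(peaks), chip, inp)
        assert len(regions) == len(truth["regions"])
        called = call_superenhancers(regions)
        supers = {(r.interval.start, r.interval.end) for r in called if r.is_super}
        planted = {(t["start"], t["end"]) for t in truth["regions"] if t["is_super"]}
        assert planted <= supers
        # signals computed from coverage match the planted net signals
        by_span = {(r.interval.start, r.interval.end): r.net_signal for r in regions}
        for t in truth["regions"]:
            assert by_span[(t["start"], t["end"])] == pytest.approx(
                t["net_signal"], rel=1e-3
            )


class TestSEBindingOverlap:
    def test_full_and_zero_overlap(self):
        ses = [region("chr1", 0, 1_000), region("chr1", 10_000, 11_000)]
        hits = [GenomicInterval("chr1", 500, 600),
                GenomicInterval("chr1", 10_500, 10_600)]
        frac, counts = se_binding_overlap(ses, hits)
        assert frac == 1.0 and counts == [1, 1]
        frac, counts = se_binding_overlap(ses, [GenomicInterval("chr2", 0, 100)])
        assert frac == 0.0

    def test_matches_brute_force(self, rng):
        ses = [region("chr1", int(s), int(s) + 2_000)
               for s in rng.integers(0, 500_000, size=50)]
        sites = [GenomicInterval("chr1", int(s), int(s) + 200)
                 for s in rng.integers(0, 500_000, size=200)]
        frac, counts = se_binding_overlap(ses, sites)
        expected = [
            sum(se.interval.overlaps(site) for site in sites) for se in ses
        ]
        assert counts == expected
        assert frac == sum(c > 0 for c in expected) / len(ses)

    def test_empty_se_set_error(self):
        with pytest.raises(ValueError):
            se_binding_overlap([], [GenomicInterval("chr1", 0, 10)])


class TestCompareSiteClasses:
    def test_identical_groups_no_difference(self, rng):
        vals = rng.normal(100, 10, size=50).tolist()
        means, table = compare_site_classes(
            {"promoter": vals, "distal": list(vals), "se": list(vals)}
        )
        assert all(p == pytest.approx(1.0) for p in table["p_adj"])

    def test_planted_means_and_reference_hsd(self, rng):
        groups = {
            "promoter": rng.normal(200, 30, 80).tolist(),
            "distal": rng.normal(270, 30, 80).tolist(),
            "se": rng.normal(390, 30, 80).tolist(),
        }
        means, table = compare_site_classes(groups)
        for name, mu in (("promoter", 200), ("distal", 270), ("se", 390)):
            sem = 30 / np.sqrt(80)
            assert abs(means[name] - mu) < 4 * sem
        # independent oracle: statsmodels Tukey HSD
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        values = np.concatenate([groups[k] for k in groups])
        labels = np.repeat(list(groups), [len(groups[k]) for k in groups])
        ref = pairwise_tukeyhsd(values, labels)
        ref_p = {
            tuple(sorted((row[0], row[1]))): p
            for row, p in zip(ref._results_table.data[1:], ref.pvalues)
        }
        for row in table.itertuples():
            key = tuple(sorted((row.group_a, row.group_b)))
            assert row.p_adj == pytest.approx(ref_p[key], abs=1e-4)

    def test_two_groups_match_t_distribution_direction(self, rng):
        a = rng.normal(0, 1, 40).tolist()
        b = rng.normal(2, 1, 40).tolist()
        means, table = compare_site_classes({"a": a, "b": b})
        assert table.loc[0, "p_adj"] < 1e-6
        means2, table2 = compare_site_classes({"a": a, "b": list(a)})
        assert table2.loc[0, "p_adj"] > 0.9

    def test_small_group_excluded(self, rng):
        with pytest.warns(UserWarning, match="excluded"):
            means, table = compare_site_classes(
                {"a": rng.normal(size=20).tolist(),
                 "b": rng.normal(size=20).tolist(),
                 "tiny": [1.0]}
            )
        assert "tiny" not in means
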