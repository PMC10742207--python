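"""Interval model, BED/GTF I/O, overlap arithmetic, and peak annotation."""

import pytest

from fusebind.intervals import (
    BedParseError,
    GeneIndex,
    GeneModel,
    GenomicInterval,
    annotate_peak_location,
    annotate_peaks,
    consensus_sites,
    intersect_intervals,
    map_peaks_to_promoters,
    nearest_genes,
    read_bed,
    read_gene_models,
    three_way_overlap_counts,
    write_bed,
)

from conftest import brute_force_overlaps, random_intervals


class TestGenomicInterval:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            GenomicInterval("chr1", 200, 100)
        with pytest.raises(ValueError):
            GenomicInterval("chr1", -1, 100)
        with pytest.raises(ValueError):
            GenomicInterval("", 0, 100)

    def test_half_open_boundary(self):
        a = GenomicInterval("chr1", 0, 10)
        assert a.overlaps(GenomicInterval("chr1", 9, 20))
        assert not a.overlaps(GenomicInterval("chr1", 10, 20))
        assert not a.overlaps(GenomicInterval("chr2", 0, 10))


class TestBedIO:
    def test_bed3_defaults(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t100\t200\n")
        (iv,) = read_bed(p)
        assert (iv.chrom, iv.start, iv.end, iv.strand) == ("chr1", 100, 200, ".")
        assert iv.name is None and iv.score is None

    def test_bed6_full(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr2\t0\t50\tpk1\t13\t-\n")
        (iv,) = read_bed(p)
        assert iv.name == "pk1" and iv.score == 13 and iv.strand == "-"

    def test_invalid_coordinates_name_line(self, tmp_path):
        p = tmp_path / "x.bed"
        p.write_text("chr1\t0\t10\nchr1\t200\t100\n")
        with pytest.raises(BedParseError, match=":2"):
            read_bed(p)

    def test_round_trip_preserves_order_and_fields(self, tmp_path, rng):
        intervals = [
            GenomicInterval("chr2", 5, 25, "-", "b", 2.5),
            GenomicInterval("chr1", 0, 10, "+", "a", 1.0),
            GenomicInterval("chr1", 100, 110),
        ]
        p = tmp_path / "rt.bed"
        write_bed(intervals, p)
        assert read_bed(p) == intervals

    def test_empty_collection(self, tmp_path):
        p = tmp_path / "empty.bed"
        write_bed([], p)
        assert read_bed(p) == []


class TestGeneModels:
    def test_gtf_coordinate_conversion(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text(
            'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "G1";\n'
            'chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tgene_id "G2";\n'
        )
        g1, g2 = read_gene_models(p, "gtf")
        assert (g1.gene_start, g1.gene_end, g1.tss) == (1000, 2000, 1000)
        assert g2.tss == 1999  # minus strand: TSS at the right edge

    def test_unknown_strand_rejected(self, tmp_path):
        p = tmp_path / "g.gtf"
        p.write_text('chr1\tsrc\tgene\t1\t100\t.\t?\t.\tgene_id "G1";\n')
        with pytest.raises(BedParseError):
            read_gene_models(p, "gtf")

    def test_gene_tsv(self, tmp_path):
        p = tmp_path / "g.tsv"
        p.write_text("gene_id\tchrom\tstrand\tstart\tend\nG1\tchr1\t-\t1000\t2000\n")
        (g,) = read_gene_models(p, "tsv")
        assert g.tss == 1999


class TestIntersect:
    def test_half_open_overlap_rules(self):
        a = [GenomicInterval("chr1", 0, 10)]
        assert intersect_intervals(a, [GenomicInterval("chr1", 9, 20)]) == a
        assert intersect_intervals(a, [GenomicInterval("chr1", 10, 20)]) == []

    def test_matches_all_pairs_oracle(self, rng):
        for _ in range(100):
            a = random_intervals(rng, int(rng.integers(1, 500)))
            b = random_intervals(rng, int(rng.integers(1, 500)))
            got = intersect_intervals(a, b, "report_a_overlapping_b")
            expected = sorted(
                set(brute_force_overlaps(a, b)),
                key=lambda iv: (iv.chrom, iv.start, iv.end),
            )
            assert sorted(set(got), key=lambda iv: (iv.chrom, iv.start, iv.end)) == expected

    def test_overlap_segments(self):
        a = [GenomicInterval("chr1", 0, 100)]
        b = [GenomicInterval("chr1", 50, 150), GenomicInterval("chr1", 90, 95)]
        segs = intersect_intervals(a, b, "report_overlap_segments")
        assert [(s.start, s.end) for s in segs] == [(50, 100), (90, 95)]

    def test_shift_invariance(self, rng):
        a = random_intervals(rng, 100)
        b = random_intervals(rng, 100)
        base = intersect_intervals(a, b)
        shifted = intersect_intervals(
            [iv.shifted(7_000) for iv in a], [iv.shifted(7_000) for iv in b]
        )
        assert [iv.shifted(7_000) for iv in base] == shifted


class TestConsensus:
    def test_identical_sets_identity(self, rng):
        s = random_intervals(rng, 50)
        assert consensus_sites([s, list(s), list(s)]) == sorted(
            s, key=lambda iv: (iv.chrom, iv.start, iv.end)
        )

    def test_empty_member_empties_consensus(self, rng):
        s = random_intervals(rng, 20)
        assert consensus_sites([s, []]) == []

    def test_requires_two_sets(self):
        with pytest.raises(ValueError):
            consensus_sites([[GenomicInterval("chr1", 0, 1)]])

    def test_planted_common_loci_recovered(self, rng):
        common = [
            GenomicInterval("chr1", 100_000 + i * 10_000, 100_200 + i * 10_000)
            for i in range(7)
        ]
        sets = []
        for k in range(3):
            private = [
                GenomicInterval("chr2", 500_000 + k * 50_000 + i * 1_000,
                                500_100 + k * 50_000 + i * 1_000)
                for i in range(10)
            ]
            sets.append(common + private)
        result = consensus_sites(sets)
        assert sorted(result, key=lambda iv: iv.start) == common

    def test_monotone_in_number_of_sets(self, rng):
        sets = [random_intervals(rng, 200) for _ in range(4)]
        sizes = [
            len(consensus_sites(sets[: k + 1])) for k in range(1, 4)
        ]
        assert sizes == sorted(sizes, reverse=True)


class TestAnnotation:
    def test_promoter_with_signed_distance(self, gene_panel):
        # gA TSS at 20,000 (+); midpoint 19,600 is 400 bp upstream
        ann = annotate_peak_location(
            GenomicInterval("chr1", 19_500, 19_700), gene_panel
        )
        assert ann.category == "promoter"
        assert ann.nearest_gene == "gA"
        assert ann.distance_to_tss == -400

    def test_minus_strand_distance_sign(self, gene_panel):
        # gB TSS at 65,999 (-); a peak left of the TSS is downstream for gB
        ann = annotate_peak_location(
            GenomicInterval("chr1", 61_000, 61_200), gene_panel
        )
        assert ann.nearest_gene == "gB"
        assert ann.distance_to_tss == 65_999 - 61_100

    def test_intragenic_beyond_promoter_window(self, gene_panel):
        # gD body 30,000-37,000 on chr2 (-): TSS at 36,999; midpoint 30,500
        ann = annotate_peak_location(
            GenomicInterval("chr2", 30_400, 30_600), gene_panel
        )
        assert ann.category == "intragenic"

    def test_promoter_precedence_over_body(self):
        genes = [
            GeneModel("host", "chr1", "+", 10_000, 50_000),
            GeneModel("neighbor", "chr1", "-", 25_000, 30_100),
        ]
        # inside host's body but within neighbor's TSS window (TSS at 30,099)
        ann = annotate_peak_location(GenomicInterval("chr1", 30_500, 30_700), genes)
        assert ann.category == "promoter"

    def test_missing_chromosome_is_intergenic(self, gene_panel):
        ann = annotate_peak_location(GenomicInterval("chrX", 0, 100), gene_panel)
        assert ann.category == "intergenic" and ann.nearest_gene is None

    def test_categories_partition_peak_set(self, rng, gene_panel):
        peaks = random_intervals(rng, 500, span=150_000)
        anns = annotate_peaks(peaks, gene_panel)
        counts = {c: sum(a.category == c for a in anns)
                  for c in ("promoter", "intragenic", "intergenic")}
        assert sum(counts.values()) == len(peaks)

    def test_shift_invariance_of_categories(self, rng, gene_panel):
        peaks = random_intervals(rng, 200, span=150_000)
        shifted_genes = [
            GeneModel(g.gene_id, g.chrom, g.strand, g.gene_start + 5_000,
                      g.gene_end + 5_000)
            for g in gene_panel
        ]
        base = [a.category for a in annotate_peaks(peaks, gene_panel)]
        moved = [
            a.category
            for a in annotate_peaks([p.shifted(5_000) for p in peaks], shifted_genes)
        ]
        assert base == moved


class TestNearestGenes:
    def test_ranked_within_cutoff(self):
        genes = [
            GeneModel("far", "chr1", "+", 500_000, 505_000),
            GeneModel("near", "chr1", "+", 200_000, 205_000),
        ]
        ga = nearest_genes(GenomicInterval("chr1", 99_900, 100_100), genes)
        assert ga.genes == ("near", "far")  # 100 kb then 400 kb

    def test_beyond_max_distance_excluded(self):
        genes = [GeneModel("far", "chr1", "+", 700_000, 705_000)]
        ga = nearest_genes(GenomicInterval("chr1", 99_900, 100_100), genes)
        assert ga.genes == ()

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(30):
            genes = [
                GeneModel(f"g{i:03d}", "chr1", "+" if rng.random() < 0.5 else "-",
                          s := int(rng.integers(0, 2_000_000)), s + 1_000)
                for i, _ in enumerate(range(40))
            ]
            peak = GenomicInterval("chr1", p := int(rng.integers(0, 2_000_000)), p + 200)
            ga = nearest_genes(peak, genes)
            mid = peak.midpoint
            expected = sorted(
                (g for g in genes if abs(mid - g.tss) <= 500_000),
                key=lambda g: (abs(mid - g.tss), g.gene_id),
            )[:2]
            assert list(ga.genes) == [g.gene_id for g in expected]


class TestPromoterMapping:
    def test_two_peaks_one_promoter(self, gene_panel):
        peaks = [
            GenomicInterval("chr1", 19_000, 19_200),
            GenomicInterval("chr1", 21_000, 21_200),
        ]
        pairs, n_genes = map_peaks_to_promoters(peaks, gene_panel)
        assert len(pairs) == 2 and n_genes == 1

    def test_peak_spanning_two_promoters(self):
        genes = [
            GeneModel("left", "chr1", "-", 5_000, 10_000),   # TSS 9,999
            GeneModel("right", "chr1", "+", 14_000, 20_000),  # TSS 14,000
        ]
        pairs, n_genes = map_peaks_to_promoters(
            [GenomicInterval("chr1", 11_500, 12_500)], genes
        )
        assert len(pairs) == 2 and n_genes == 2

    def test_planted_pairs_recovered(self, gene_panel):
        # one peak in each promoter of the panel
        peaks = [
            GenomicInterval(g.chrom, g.tss - 100, g.tss + 100) for g in gene_panel
        ]
        pairs, n_genes = map_peaks_to_promoters(peaks, gene_panel)
        assert n_genes == len(gene_panel)
        assert {gid for _, gid in pairs} == {g.gene_id for g in gene_panel}


class TestThreeWayOverlap:
    def test_identical_sets_all_triple(self, rng):
        s = random_intervals(rng, 30)
        counts = three_way_overlap_counts(s, list(s), list(s))
        assert counts["A"]["ABC"] == 30 and counts["A"]["A_only"] == 0

    def test_disjoint_sets_all_singletons(self):
        a = [GenomicInterval("chr1", 0, 10)]
        b = [GenomicInterval("chr1", 100, 110)]
        c = [GenomicInterval("chr2", 0, 10)]
        counts = three_way_overlap_counts(a, b, c)
        assert counts["A"]["A_only"] == 1
        assert counts["B"]["B_only"] == 1
        assert counts["C"]["C_only"] == 1

    def test_matches_brute_force_tally(self, rng):
        for _ in range(20):
            a = random_intervals(rng, 100)
            b = random_intervals(rng, 100)
            c = random_intervals(rng, 100)
            counts = three_way_overlap_counts(a, b, c)
            for iv_set, anchor, o1, o2, s1, s2 in [
                (a, "A", "B", "C", b, c),
                (b, "B", "A", "C", a, c),
                (c, "C", "A", "B", a, b),
            ]:
                tally = {f"{anchor}_only": 0, f"{anchor}{o1}": 0,
                         f"{anchor}{o2}": 0, f"{anchor}{o1}{o2}": 0}
                for iv in iv_set:
                    h1 = bool(brute_force_overlaps([iv], s1))
                    h2 = bool(brute_force_overlaps([iv], s2))
                    key = (f"{anchor}{o1}{o2}" if h1 and h2
                           else f"{anchor}{o1}" if h1
                           else f"{anchor}{o2}" if h2
                           else f"{anchor}_only")
                    tally[key] += 1
                assert counts[anchor] == tally
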