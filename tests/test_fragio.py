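"""Fragment I/O: dialects, filters, bins, BED parsing, track round trips."""

import numpy as np
import pytest

from fragkit.fragio import (
    FilterSpec,
    FragFileError,
    Fragment,
    GenomicInterval,
    IntervalSet,
    filter_file,
    make_genome_bins,
    parse_bed,
    read_bedgraph,
    read_chrom_sizes,
    read_fragments,
    write_fragfile,
    write_track,
)
from fragkit.synth import fragments_to_bam, simulate_fragments


def write_frag_lines(path, lines):
    import pysam

    plain = str(path)[:-3]
    with open(plain, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    pysam.tabix_compress(plain, str(path), force=True)
    pysam.tabix_index(str(path), preset="bed", force=True)


class TestFragmentType:
    def test_invalid_intervals_rejected(self):
        with pytest.raises(ValueError):
            Fragment("chr1", 100, 100)
        with pytest.raises(ValueError):
            Fragment("chr1", -1, 100)

    def test_breakpoints_and_length(self):
        f = Fragment("chr1", 99, 266, 60, "+")
        assert f.length == 167
        assert f.midpoint == (99 + 265) // 2


class TestReadFragments:
    def test_field_mapping(self, tmp_path):
        path = tmp_path / "one.frag.gz"
        write_frag_lines(path, ["chr1\t99\t266\t60\t+"])
        [f] = read_fragments(path)
        assert f == Fragment("chr1", 99, 266, 60, "+")
        assert f.length == 167

    def test_mapq_threshold_excludes(self, tmp_path):
        path = tmp_path / "one.frag.gz"
        write_frag_lines(path, ["chr1\t99\t266\t60\t+"])
        assert list(read_fragments(path, filt=FilterSpec(min_mapq=61))) == []

    def test_mapq_filter_count(self, tmp_path):
        lines = [f"chr1\t{100 + 10 * i}\t{300 + 10 * i}\t{mq}\t+"
                 for i, mq in enumerate([60, 10, 60, 29, 60, 60, 5, 60, 60, 60])]
        path = tmp_path / "ten.frag.gz"
        write_frag_lines(path, lines)
        assert len(list(read_fragments(path))) == 7

    def test_malformed_line_names_line_number(self, tmp_path):
        path = tmp_path / "bad.frag.gz"
        plain = tmp_path / "bad.frag"
        plain.write_text("chr1\t100\t200\t60\t+\nchr1\t300\t250\t60\t+\n")
        import pysam

        pysam.tabix_compress(str(plain), str(path), force=True)
        with pytest.raises(FragFileError, match="line 2"):
            list(read_fragments(path))

    def test_region_query_unknown_contig(self, toy_fragfile):
        with pytest.raises(KeyError):
            list(read_fragments(toy_fragfile, GenomicInterval("chrX", 0, 100)))

    def test_region_query_returns_overlaps_sorted(self, toy_fragfile, toy_fragments):
        region = GenomicInterval("chr1", 10_000, 20_000)
        got = list(read_fragments(toy_fragfile, region))
        expected = sorted(
            (f for f in toy_fragments if f.start < region.end and f.end > region.start),
            key=lambda f: (f.start, f.end, f.strand),
        )
        assert got == expected

    def test_determinism_two_reads_identical(self, toy_fragfile):
        region = GenomicInterval("chr1", 5_000, 15_000)
        assert list(read_fragments(toy_fragfile, region)) == list(
            read_fragments(toy_fragfile, region)
        )


class TestDialectEquivalence:
    def test_bam_and_fragfile_yield_identical_fragments(self, tmp_path):
        frags = simulate_fragments(300, {"chr1": 50_000, "chr2": 30_000}, seed=3)
        fragfile = tmp_path / "d.frag.gz"
        write_fragfile(frags, fragfile, contig_order=["chr1", "chr2"])
        bam = tmp_path / "d.bam"
        fragments_to_bam(frags, {"chr1": 50_000, "chr2": 30_000}, bam)
        from_frag = list(read_fragments(fragfile))
        from_bam = sorted(
            read_fragments(bam), key=lambda f: (f.contig, f.start, f.end, f.strand)
        )
        assert from_frag == from_bam

    def test_bam_region_query_matches_fragfile(self, tmp_path):
        frags = simulate_fragments(300, {"chr1": 50_000}, seed=4)
        fragfile = tmp_path / "r.frag.gz"
        write_fragfile(frags, fragfile)
        bam = tmp_path / "r.bam"
        fragments_to_bam(frags, {"chr1": 50_000}, bam)
        region = GenomicInterval("chr1", 20_000, 25_000)
        a = sorted(read_fragments(fragfile, region), key=lambda f: (f.start, f.end, f.strand))
        b = sorted(read_fragments(bam, region), key=lambda f: (f.start, f.end, f.strand))
        assert a == b


class TestFilterSpec:
    def test_length_bounds_validated(self):
        with pytest.raises(ValueError):
            FilterSpec(min_length=200, max_length=100)

    def test_filters_compose_conjunctively(self):
        filt = FilterSpec(min_mapq=30, min_length=100, max_length=200)
        assert filt.passes(Fragment("chr1", 0, 150, 60))
        assert not filt.passes(Fragment("chr1", 0, 150, 10))
        assert not filt.passes(Fragment("chr1", 0, 50, 60))

    def test_blacklist_whitelist(self):
        bl = IntervalSet([GenomicInterval("chr1", 1000, 2000)])
        assert not FilterSpec(blacklist=bl).passes(Fragment("chr1", 1500, 1700, 60))
        assert FilterSpec(blacklist=bl).passes(Fragment("chr1", 3000, 3200, 60))
        assert FilterSpec(whitelist=bl).passes(Fragment("chr1", 1500, 1700, 60))
        assert not FilterSpec(whitelist=bl).passes(Fragment("chr1", 3000, 3200, 60))

    def test_monotonicity_raising_mapq_never_gains(self, toy_fragfile):
        counts = [
            len(list(read_fragments(toy_fragfile, filt=FilterSpec(min_mapq=q))))
            for q in (0, 30, 60, 61)
        ]
        assert counts == sorted(counts, reverse=True)


class TestFilterFile:
    def test_identity_filter_round_trips(self, tmp_path, toy_fragfile, toy_fragments):
        out = tmp_path / "out.frag.gz"
        n = filter_file(toy_fragfile, FilterSpec(min_mapq=0), out)
        assert n == len(toy_fragments)
        assert list(read_fragments(out)) == list(read_fragments(toy_fragfile))

    def test_length_window_retains_in_range(self, tmp_path):
        lengths = [150, 165, 170, 180, 140, 190, 175, 200, 130, 162]
        lines = [f"chr1\t{i * 1000}\t{i * 1000 + n}\t60\t+" for i, n in enumerate(lengths, 1)]
        src = tmp_path / "in.frag.gz"
        write_frag_lines(src, lines)
        out = tmp_path / "out.frag.gz"
        n = filter_file(src, FilterSpec(min_length=160, max_length=180), out)
        assert n == sum(1 for x in lengths if 160 <= x <= 180) == 5
        assert all(160 <= f.length <= 180 for f in read_fragments(out))

    def test_empty_input_gives_valid_empty_output(self, tmp_path):
        import pysam

        plain = tmp_path / "empty.frag"
        plain.write_text("")
        src = tmp_path / "empty.frag.gz"
        pysam.tabix_compress(str(plain), str(src), force=True)
        out = tmp_path / "out.frag.gz"
        assert filter_file(src, FilterSpec(), out) == 0
        assert list(read_fragments(out)) == []


class TestGenomeBins:
    def test_partial_final_bin(self):
        bins = make_genome_bins({"chr1": 250_000}, 100_000)
        assert [(b.start, b.end) for b in bins] == [
            (0, 100_000), (100_000, 200_000), (200_000, 250_000)
        ]

    def test_exact_multiple_no_empty_bin(self):
        assert len(make_genome_bins({"chr1": 200_000}, 100_000)) == 2

    def test_multi_contig_and_subset(self):
        sizes = {"chr1": 300_000, "chr2": 50_000}
        assert len(make_genome_bins(sizes, 100_000)) == 4
        assert len(make_genome_bins(sizes, 100_000, contigs=["chr2"])) == 1

    def test_conservation_of_length(self):
        sizes = {"chr1": 123_456, "chr2": 77_001}
        bins = make_genome_bins(sizes, 10_000)
        assert sum(b.length for b in bins) == sum(sizes.values())

    def test_bad_bin_size(self):
        with pytest.raises(ValueError):
            make_genome_bins({"chr1": 1000}, 0)


class TestParseBed:
    def test_bed3_and_bed6(self, tmp_path):
        p = tmp_path / "a.bed"
        p.write_text("track name=x\nchr1\t0\t100\nchr2\t5\t50\tsiteA\t0\t-\n")
        ivs = parse_bed(p)
        assert len(ivs) == 2
        assert ivs[0] == GenomicInterval("chr1", 0, 100)
        assert ivs[1].name == "siteA" and ivs[1].strand == "-"

    def test_invalid_coordinates_error_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t0\t100\nchr1\t200\t100\n")
        with pytest.raises(FragFileError, match="line 2"):
            parse_bed(p)


class TestChromSizes:
    def test_parse(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr2\t500\n")
        assert read_chrom_sizes(p) == {"chr1": 1000, "chr2": 500}

    def test_duplicate_contig_rejected(self, tmp_path):
        p = tmp_path / "g.sizes"
        p.write_text("chr1\t1000\nchr1\t500\n")
        with pytest.raises(FragFileError):
            read_chrom_sizes(p)


class TestWriteTrack:
    def test_equal_value_runs_merged(self, tmp_path):
        out = tmp_path / "t.bedgraph"
        write_track([("chr1", 0, 1, 2.0), ("chr1", 1, 2, 2.0)], out)
        assert read_bedgraph(out) == [("chr1", 0, 2, 2.0)]

    def test_empty_track(self, tmp_path):
        out = tmp_path / "e.bedgraph"
        write_track([], out)
        assert read_bedgraph(out) == []

    def test_round_trip_distinct_values(self, tmp_path):
        recs = [("chr1", i, i + 1, float(i)) for i in range(5)]
        out = tmp_path / "r.bedgraph"
        write_track(recs, out)
        assert read_bedgraph(out) == recs

    def test_unsorted_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_track([("chr1", 10, 11, 1.0), ("chr1", 0, 1, 2.0)], tmp_path / "x")

    def test_bigwig_round_trip(self, tmp_path):
        import pyBigWig

        recs = [("chr1", 0, 10, 1.5), ("chr1", 10, 20, -2.0)]
        out = tmp_path / "t.bw"
        write_track(recs, out, format="bigwig", sizes={"chr1": 1000})
        bw = pyBigWig.open(str(out))
        vals = bw.values("chr1", 0, 20)
        assert np.allclose(vals[:10], 1.5) and np.allclose(vals[10:], -2.0)
        bw.close()
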