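"""Interval model, BED/GTF I/O and the overlap/set-algebra engine."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from glycochrom.intervals import (
    GenomeSpec,
    GenomicInterval,
    PeakSet,
    intersect_regions,
    merge,
    overlaps,
    read_bed,
    read_genes,
    subtract,
    union,
    window_around_point,
    write_bed,
)

from conftest import bitmap, random_peakset


# ---------------------------------------------------------------------------
# Data model
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("start,end", [(-1, 5), (5, 5), (7, 3)])
def test_invalid_interval_rejected(start, end):
    with pytest.raises(ValueError):
        GenomicInterval("chr1", start, end)


def test_peakset_sorted_and_genome_validated():
    ivs = [GenomicInterval("chr1", 500, 700), GenomicInterval("chr1", 100, 300)]
    ps = PeakSet(ivs)
    assert [(iv.start, iv.end) for iv in ps] == [(100, 300), (500, 700)]
    with pytest.raises(ValueError, match="exceeds"):
        PeakSet(ivs, genome=GenomeSpec({"chr1": 600}))


def test_effective_size_cannot_exceed_genome():
    with pytest.raises(ValueError):
        GenomeSpec({"chr1": 100}, effective_size=200)


def test_gene_model_strand_aware_anchors():
    from glycochrom.intervals import GeneModel

    g = GeneModel("a", "chr1", 1000, 2000, "+")
    assert (g.tss, g.tes) == (1000, 1999)
    g = GeneModel("b", "chr1", 1000, 2000, "-")
    assert (g.tss, g.tes) == (1999, 1000)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def test_read_bed_field_mapping_and_sorting(tmp_path):
    p = tmp_path / "a.bed"
    p.write_text("chr1\t500\t700\nchr1\t100\t300\n")
    ps = read_bed(p)
    assert [(iv.chrom, iv.start, iv.end, iv.strand) for iv in ps] == [
        ("chr1", 100, 300, "."),
        ("chr1", 500, 700, "."),
    ]


def test_read_bed_empty_and_errors(tmp_path):
    empty = tmp_path / "e.bed"
    empty.write_text("")
    assert len(read_bed(empty)) == 0
    bad = tmp_path / "b.bed"
    bad.write_text("chr1\t100\n")
    with pytest.raises(ValueError, match="b.bed:1"):
        read_bed(bad)
    inverted = tmp_path / "i.bed"
    inverted.write_text("chr1\t100\t300\nchr1\t300\t200\n")
    with pytest.raises(ValueError, match="i.bed:2"):
        read_bed(inverted)


def test_read_narrowpeak_summit_and_field_count(tmp_path):
    p = tmp_path / "a.narrowPeak"
    p.write_text("chr1\t100\t400\tpk1\t850\t.\t12.1\t9.9\t7.7\t151\n")
    ps = read_bed(p, format="narrowPeak")
    assert ps[0].name == "pk1" and ps[0].score == 850
    assert ps.summits[ps[0]] == 151
    short = tmp_path / "s.narrowPeak"
    short.write_text("chr1\t100\t400\n")
    with pytest.raises(ValueError, match="10 fields"):
        read_bed(short, format="narrowPeak")


def test_bed_round_trip_bit_exact(tmp_path):
    rng = np.random.default_rng(11)
    ps = random_peakset(rng, 50, chroms=("chrA", "chrB"))
    out = tmp_path / "rt.bed"
    write_bed(ps, out)
    back = read_bed(out)
    assert [(iv.chrom, iv.start, iv.end) for iv in back] == [
        (iv.chrom, iv.start, iv.end) for iv in ps
    ]


def test_read_genes_gtf_coordinate_conversion(tmp_path):
    gtf = tmp_path / "g.gtf"
    gtf.write_text(
        'chr1\tsrc\tgene\t1001\t2000\t.\t+\t.\tgene_id "gp";\n'
        'chr1\tsrc\tgene\t1001\t2000\t.\t-\t.\tgene_id "gm";\n'
        'chr1\tsrc\texon\t1001\t1100\t.\t+\t.\tgene_id "gp";\n'
    )
    genes = read_genes(gtf, "gtf")
    assert len(genes) == 2  # exon line ignored
    gp, gm = genes
    assert (gp.start, gp.end, gp.tss, gp.tes) == (1000, 2000, 1000, 1999)
    assert (gm.tss, gm.tes) == (1999, 1000)


def test_read_genes_rejects_duplicates_and_missing_strand(tmp_path):
    gtf = tmp_path / "g.gtf"
    gtf.write_text(
        'chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "a";\n'
        'chr1\ts\tgene\t200\t300\t.\t.\t.\tgene_id "b";\n'
    )
    with pytest.warns(UserWarning, match="no strand"):
        genes = read_genes(gtf, "gtf")
    assert [g.gene_id for g in genes] == ["a"]
    dup = tmp_path / "d.gtf"
    dup.write_text(
        'chr1\ts\tgene\t1\t100\t.\t+\t.\tgene_id "a";\n'
        'chr1\ts\tgene\t200\t300\t.\t+\t.\tgene_id "a";\n'
    )
    with pytest.raises(ValueError, match="duplicate"):
        read_genes(dup, "gtf")
    empty = tmp_path / "e.gtf"
    empty.write_text("")
    assert read_genes(empty, "gtf") == []


# ---------------------------------------------------------------------------
# Overlaps
# ---------------------------------------------------------------------------


def test_half_open_abutment_is_not_overlap():
    a = PeakSet([GenomicInterval("chr1", 0, 100)])
    b = PeakSet([GenomicInterval("chr1", 100, 200)])
    assert overlaps(a, b)[a[0]] == []


def test_single_base_overlap_counts():
    a = PeakSet([GenomicInterval("chr1", 0, 100)])
    b = PeakSet([GenomicInterval("chr1", 99, 200)])
    assert overlaps(a, b)[a[0]] == [b[0]]
    assert overlaps(a, b, min_bp=2)[a[0]] == []


def test_cross_chromosome_never_overlaps():
    a = PeakSet([GenomicInterval("chr1", 0, 100)])
    b = PeakSet([GenomicInterval("chr2", 0, 100)])
    with pytest.warns(UserWarning, match="no shared chromosome"):
        assert overlaps(a, b)[a[0]] == []


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_overlaps_matches_all_pairs_bruteforce(seed):
    rng = np.random.default_rng(seed)
    a = random_peakset(rng, 50, chroms=("chrA", "chrB"))
    b = random_peakset(rng, 50, chroms=("chrA", "chrB"))
    got = overlaps(a, b, min_bp=1)
    for iv in a:
        expected = [jv for jv in b if iv.overlap_bp(jv) >= 1]
        assert got[iv] == expected


@pytest.mark.parametrize("seed", [3, 4])
def test_overlap_hit_existence_is_symmetric(seed):
    rng = np.random.default_rng(seed)
    a = random_peakset(rng, 40)
    b = random_peakset(rng, 40)
    ab = overlaps(a, b, min_bp=5)
    ba = overlaps(b, a, min_bp=5)
    hits_ab = {(x, y) for x, ys in ab.items() for y in ys}
    hits_ba = {(x, y) for y, xs in ba.items() for x in xs}
    assert hits_ab == hits_ba


# ---------------------------------------------------------------------------
# Windows
# ---------------------------------------------------------------------------


def test_window_basic_and_clipped():
    w = window_around_point("chr1", 5000, 1000)
    assert (w.start, w.end) == (4000, 6001)
    genome = GenomeSpec({"chr1": 10_000})
    w = window_around_point("chr1", 200, 1000, genome)
    assert (w.start, w.end) == (0, 1201)
    w = window_around_point("chr1", 9900, 1000, genome)
    assert (w.start, w.end) == (8900, 10_000)


def test_window_errors():
    with pytest.raises(ValueError):
        window_around_point("chr1", 100, 0)
    with pytest.raises(ValueError, match="outside"):
        window_around_point("chr1", 20_000, 100, GenomeSpec({"chr1": 10_000}))


# ---------------------------------------------------------------------------
# Set algebra vs per-base bitmap oracle
# ---------------------------------------------------------------------------


def test_merge_and_intersect_hand_examples():
    a = PeakSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 50, 150)])
    assert [(iv.start, iv.end) for iv in merge(a)] == [(0, 150)]
    b = PeakSet([GenomicInterval("c", 50, 150)])
    a1 = PeakSet([GenomicInterval("c", 0, 100)])
    assert [(iv.start, iv.end) for iv in intersect_regions(a1, b)] == [(50, 100)]


def test_merge_collapses_abutting():
    a = PeakSet([GenomicInterval("c", 0, 100), GenomicInterval("c", 100, 200)])
    assert [(iv.start, iv.end) for iv in merge(a)] == [(0, 200)]


def _assert_algebra_matches_bitmap(a: PeakSet, b: PeakSet, length: int = 100_000):
    ma, mb = bitmap(a, "chrA", length), bitmap(b, "chrA", length)
    cases = {
        "merge": (merge(a), ma),
        "intersect": (intersect_regions(a, b), ma & mb),
        "union": (union(a, b), ma | mb),
        "subtract": (subtract(a, b), ma & ~mb),
    }
    for name, (got, expected_mask) in cases.items():
        got_mask = bitmap(got, "chrA", length)
        assert np.array_equal(got_mask, expected_mask), name
        # outputs sorted and non-overlapping
        prev_end = -1
        for iv in got:
            assert iv.start >= prev_end, name
            prev_end = iv.end


@pytest.mark.parametrize("seed", range(5))
def test_set_algebra_matches_bitmap_oracle(seed):
    rng = np.random.default_rng(seed)
    a = random_peakset(rng, int(rng.integers(1, 60)))
    b = random_peakset(rng, int(rng.integers(1, 60)))
    _assert_algebra_matches_bitmap(a, b)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_set_algebra_bitmap_property(seed):
    rng = np.random.default_rng(seed)
    a = random_peakset(rng, int(rng.integers(1, 30)), chrom_len=10_000, max_width=500)
    b = random_peakset(rng, int(rng.integers(1, 30)), chrom_len=10_000, max_width=500)
    _assert_algebra_matches_bitmap(a, b, length=10_000)


def test_algebra_against_bedtools(tmp_path):
    """Independent cross-check of merge/intersect against bedtools."""
    import shutil
    import subprocess

    if shutil.which("bedtools") is None:
        pytest.skip("bedtools not on PATH")
    rng = np.random.default_rng(99)
    a, b = random_peakset(rng, 40), random_peakset(rng, 40)
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(a, fa)
    write_bed(b, fb)

    def run(cmd):
        out = subprocess.run(cmd, capture_output=True, text=True, check=True).stdout
        return [
            (f[0], int(f[1]), int(f[2]))
            for f in (line.split("\t") for line in out.strip().split("\n") if line)
        ]

    sa = tmp_path / "a.sorted.bed"
    sa.write_text(
        "".join(f"{iv.chrom}\t{iv.start}\t{iv.end}\n" for iv in a)
    )
    assert run(["bedtools", "merge", "-i", str(sa)]) == [
        (iv.chrom, iv.start, iv.end) for iv in merge(a)
    ]
    got = run(["bedtools", "intersect", "-a", str(sa), "-b", str(fb)])
    # bedtools reports per-input-interval pieces; merge both sides to compare coverage
    ours = intersect_regions(a, b)
    merged_theirs = merge(PeakSet([GenomicInterval(c, s, e) for c, s, e in got]))
    assert [(iv.chrom, iv.start, iv.end) for iv in merged_theirs] == [
        (iv.chrom, iv.start, iv.end) for iv in ours
    ]
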