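"""Interval algebra vs brute-force oracles and bedtools."""

import shutil
import subprocess

import pytest

from crmscan import (ANY_OVERLAP, GenomicInterval, Transcript,
                     intersect_report_a, merge, nearest_transcript,
                     total_covered_bp, write_bed)
from conftest import random_intervals


def overlap_bp(a, b):
    if a.chrom != b.chrom:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def brute_force_intersect(a, b, min_b_fraction):
    """All-pairs oracle for report-A/unique semantics."""
    out = []
    for iv in a:
        for bv in b:
            ov = overlap_bp(iv, bv)
            if ov >= 1 and ov >= min_b_fraction * bv.length:
                out.append(iv)
                break
    return out


def brute_force_nearest(query, transcripts):
    best = None
    for t in transcripts:
        if t.interval.chrom != query.chrom:
            continue
        if overlap_bp(query, t.interval):
            d = 0
        elif t.interval.start >= query.end:
            d = t.interval.start - query.end
        else:
            d = query.start - t.interval.end
        key = (d, t.interval.start, t.transcript_id)
        if best is None or key < best[0]:
            best = (key, t)
    return (None, None) if best is None else (best[1], best[0][0])


# --- intersect_report_a -----------------------------------------------------

def test_full_containment_returns_anchor():
    a = [GenomicInterval("chr1", 100, 200)]
    b = [GenomicInterval("chr1", 120, 128)]
    assert intersect_report_a(a, b, 1.0) == a


def test_straddling_feature_fails_full_containment_passes_any_overlap():
    a = [GenomicInterval("chr1", 100, 200)]
    b = [GenomicInterval("chr1", 195, 205)]
    assert intersect_report_a(a, b, 1.0) == []
    assert intersect_report_a(a, b, ANY_OVERLAP) == a


def test_coextensive_feature_counts_as_contained():
    a = [GenomicInterval("chr1", 100, 200)]
    b = [GenomicInterval("chr1", 100, 200)]
    assert intersect_report_a(a, b, 1.0) == a


def test_multiple_contained_features_report_anchor_once():
    a = [GenomicInterval("chr1", 100, 200)]
    b = [GenomicInterval("chr1", 110, 115), GenomicInterval("chr1", 120, 125),
         GenomicInterval("chr1", 130, 135)]
    assert intersect_report_a(a, b, 1.0) == a


def test_output_preserves_input_order_and_objects(rng):
    a = random_intervals(rng, 40)
    b = random_intervals(rng, 60)
    kept = intersect_report_a(a, b, ANY_OVERLAP)
    positions = [a.index(iv) for iv in kept]
    assert positions == sorted(positions)
    assert all(any(k is orig for orig in a) for k in kept)


@pytest.mark.parametrize("fraction", [ANY_OVERLAP, 0.5, 1.0])
def test_intersect_matches_all_pairs_oracle(rng, fraction):
    for _ in range(20):
        a = random_intervals(rng, int(rng.integers(1, 60)))
        b = random_intervals(rng, int(rng.integers(1, 120)))
        assert intersect_report_a(a, b, fraction) == \
            brute_force_intersect(a, b, fraction)


def test_fraction_monotonicity(rng):
    a = random_intervals(rng, 80)
    b = random_intervals(rng, 150)
    strict = set(map(id, intersect_report_a(a, b, 1.0)))
    loose = set(map(id, intersect_report_a(a, b, 0.25)))
    assert strict <= loose


def test_enlarging_b_never_removes_results(rng):
    a = random_intervals(rng, 50)
    b = random_intervals(rng, 60)
    b_extra = b + random_intervals(rng, 40)
    assert set(map(id, intersect_report_a(a, b, 1.0))) <= \
        set(map(id, intersect_report_a(a, b_extra, 1.0)))


@pytest.mark.skipif(shutil.which("bedtools") is None,
                    reason="bedtools unavailable")
@pytest.mark.parametrize("args, fraction", [
    (["-F", "1.0"], 1.0),
    ([], ANY_OVERLAP),
])
def test_intersect_matches_bedtools(rng, tmp_path, args, fraction):
    """Independent cross-check against bedtools intersect -wa -u."""
    a = sorted(random_intervals(rng, 80),
               key=lambda iv: (iv.chrom, iv.start, iv.end))
    b = sorted(random_intervals(rng, 120),
               key=lambda iv: (iv.chrom, iv.start, iv.end))
    fa, fb = tmp_path / "a.bed", tmp_path / "b.bed"
    write_bed(a, fa)
    write_bed(b, fb)
    res = subprocess.run(
        ["bedtools", "intersect", "-a", str(fa), "-b", str(fb), "-wa", "-u"]
        + args, capture_output=True, text=True, check=True)
    expected = [tuple(line.split("\t")[:3]) for line in res.stdout.splitlines()]
    ours = [(iv.chrom, str(iv.start), str(iv.end))
            for iv in intersect_report_a(a, b, fraction)]
    assert ours == expected


# --- merge ------------------------------------------------------------------

def test_merge_overlapping_and_abutting():
    assert merge([GenomicInterval("chr1", 100, 200),
                  GenomicInterval("chr1", 150, 250)]) == \
        [GenomicInterval("chr1", 100, 250)]
    assert merge([GenomicInterval("chr1", 100, 200),
                  GenomicInterval("chr1", 200, 300)]) == \
        [GenomicInterval("chr1", 100, 300)]


def test_merge_covered_bp_matches_position_marking_oracle(rng):
    ivs = random_intervals(rng, 70, max_pos=400, max_len=50)
    marked = {(iv.chrom, p) for iv in ivs for p in range(iv.start, iv.end)}
    assert total_covered_bp(ivs) == len(marked)
    merged = merge(ivs)
    assert all(x.end <= y.start or x.chrom != y.chrom
               for x, y in zip(merged, merged[1:]))


# --- nearest transcript -----------------------------------------------------

def tx(chrom, start, end, tid, gid=None):
    return Transcript(GenomicInterval(chrom, start, end),
                      transcript_id=tid, gene_id=gid or tid)


def test_overlap_gives_distance_zero():
    t, d = nearest_transcript(GenomicInterval("chr1", 100, 200),
                              [tx("chr1", 150, 400, "t1")])
    assert (t.transcript_id, d) == ("t1", 0)


def test_equidistant_tie_breaks_to_smaller_start():
    t, d = nearest_transcript(
        GenomicInterval("chr1", 100, 200),
        [tx("chr1", 250, 300, "a"), tx("chr1", 0, 50, "b")])
    assert (t.transcript_id, d) == ("b", 50)


def test_tie_at_same_start_breaks_lexicographically():
    t, _ = nearest_transcript(
        GenomicInterval("chr1", 100, 200),
        [tx("chr1", 250, 300, "zz"), tx("chr1", 250, 320, "aa")])
    assert t.transcript_id == "aa"


def test_other_chromosomes_ineligible_with_warning(caplog):
    with caplog.at_level("WARNING", logger="crmscan"):
        t, d = nearest_transcript(GenomicInterval("chr9", 0, 10),
                                  [tx("chr1", 0, 10, "t1")])
    assert (t, d) == (None, None)


def test_empty_transcript_set_errors():
    with pytest.raises(ValueError, match="empty"):
        nearest_transcript(GenomicInterval("chr1", 0, 10), [])


def test_nearest_matches_all_pairs_oracle(rng):
    txs = [tx("chr" + str(int(rng.integers(1, 3))), s, s + w, f"t{i}")
           for i, (s, w) in enumerate(zip(rng.integers(0, 2000, 60),
                                          rng.integers(1, 300, 60)))]
    for q in random_intervals(rng, 50, chroms=("chr1", "chr2"), max_pos=2000):
        got = nearest_transcript(q, txs)
        exp = brute_force_nearest(q, txs)
        assert (got[0].transcript_id if got[0] else None,
                got[1]) == (exp[0].transcript_id if exp[0] else None, exp[1])


def test_nearest_distance_symmetric_under_mirroring(rng):
    """Mirroring every coordinate (x -> L - x) preserves the distance."""
    L = 5000
    txs = [tx("chr1", s, s + w, f"t{i}")
           for i, (s, w) in enumerate(zip(rng.integers(0, 4000, 30),
                                          rng.integers(1, 400, 30)))]
    mirrored = [tx("chr1", L - t.interval.end, L - t.interval.start,
                   t.transcript_id) for t in txs]
    for q in random_intervals(rng, 30, chroms=("chr1",), max_pos=4000):
        mq = GenomicInterval("chr1", L - q.end, L - q.start)
        assert nearest_transcript(q, txs)[1] == \
            nearest_transcript(mq, mirrored)[1]
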