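"""Interval-set algebra: containment-aware intersection with
report-A/unique semantics, merging, and nearest-transcript search.

``intersect_report_a`` mirrors ``bedtools intersect -wa -u`` with the
overlap requirement anchored on the B feature (``-F``): an A interval is
reported, once, with unchanged coordinates, iff some B interval on the
same chromosome overlaps it by at least ``min_b_fraction`` of that B
interval's length (and by at least 1 bp).  ``min_b_fraction=1.0`` is
full containment of the B feature — the reading under which "motif
fully inside peak" is expressible — and :data:`ANY_OVERLAP` reproduces
the default >=1 bp overlap.

Strand is ignored throughout: peaks are unstranded and a motif hit on
either strand may satisfy containment.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from typing import Sequence

from intervaltree import IntervalTree

from .formats_io import GenomicInterval, Transcript, as_interval

logger = logging.getLogger("crmscan")

#: ``min_b_fraction`` value that reduces the requirement to >=1 bp overlap
#: (the bedtools default fraction).
ANY_OVERLAP = 1e-9


def _trees_by_chrom(records) -> dict:
    trees: dict[str, IntervalTree] = defaultdict(IntervalTree)
    for rec in records:
        iv = as_interval(rec)
        trees[iv.chrom].addi(iv.start, iv.end, iv)
    return trees


def intersect_report_a(a, b, min_b_fraction: float = 1.0) -> list:
    """Return the A records (input order, original objects, no duplicates)
    for which some B interval overlaps by >= ``min_b_fraction`` x len(B).

    A B feature exactly coextensive with an A interval counts as fully
    contained (overlap == len(B) satisfies >= 1.0 x len(B)).
    """
    if not (0 < min_b_fraction <= 1):
        raise ValueError(f"min_b_fraction must lie in (0, 1], got {min_b_fraction}")
    trees = _trees_by_chrom(b)
    out = []
    for rec in a:
        iv = as_interval(rec)
        tree = trees.get(iv.chrom)
        if tree is None:
            continue
        for node in tree.overlap(iv.start, iv.end):
            b_iv = node.data
            overlap = min(iv.end, b_iv.end) - max(iv.start, b_iv.start)
            if overlap >= 1 and overlap >= min_b_fraction * b_iv.length:
                out.append(rec)
                break
    return out


def merge(intervals) -> list:
    """Union-preserving merge into sorted, non-overlapping intervals.
    Abutting intervals (end == next start) are merged."""
    ivs = sorted((as_interval(r) for r in intervals),
                 key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in ivs:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end)
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return out


def total_covered_bp(intervals) -> int:
    return sum(iv.length for iv in merge(intervals))


def interval_distance(a: GenomicInterval, b: GenomicInterval) -> int:
    """Unsigned gap between closest edges; 0 when the intervals overlap.
    Caller guarantees a shared chromosome."""
    if a.chrom != b.chrom:
        raise ValueError("distance undefined across chromosomes")
    if a.start < b.end and b.start < a.end:
        return 0
    return b.start - a.end if a.end <= b.start else a.start - b.end


def nearest_transcript(query, transcripts: Sequence[Transcript]):
    """The nearest transcript to *query* and its unsigned distance in bp.

    Distance is 0 on any overlap, otherwise the gap between closest
    edges.  Ties break toward the smaller transcript start, then the
    lexicographically smaller transcript_id.  Transcripts on other
    chromosomes are ineligible; if none shares the chromosome, returns
    ``(None, None)`` with a warning.  An empty transcript set is an error.
    """
    if not transcripts:
        raise ValueError("transcript set is empty")
    iv = as_interval(query)
    best = None
    for t in transcripts:
        if t.interval.chrom != iv.chrom:
            continue
        d = interval_distance(iv, t.interval)
        key = (d, t.interval.start, t.transcript_id)
        if best is None or key < best[0]:
            best = (key, t)
    if best is None:
        logger.warning("no transcript on chromosome %s; query %s:%d-%d left "
                       "unannotated", iv.chrom, iv.chrom, iv.start, iv.end)
        return None, None
    return best[1], best[0][0]


def annotate_nearest(queries, transcripts: Sequence[Transcript]) -> list:
    """Batch :func:`nearest_transcript`, one (transcript, distance) per query."""
    return [nearest_transcript(q, transcripts) for q in queries]
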