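"""PWM scoring and genome scanning with percent-of-maximum thresholds.

A window of width W is scored as the sum of the matrix weight of its
observed base at each position; a hit is retained iff its score reaches
a configurable fraction of the matrix's highest attainable score
(default 0.80).  This reproduces the semantics of scanning a
probability matrix with a percentage ``min.score`` in
Biostrings::matchPWM, applied per chromosome.

Both strands are scanned by default.  The minus strand is scanned by
scoring the forward sequence with the reverse-complemented matrix, so
hit coordinates always refer to the forward strand; the hit's strand
field records which orientation scored.

Windows containing ``N`` are disqualified outright rather than scored
with a partial sum, which avoids threshold-dependent artifacts at
assembly gaps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .formats_io import BASE_INDEX, GenomicInterval, PWM

logger = logging.getLogger("crmscan")

__all__ = [
    "PWM", "MotifHit", "window_score", "threshold_from_fraction",
    "scan_sequence", "reverse_complement", "log_odds",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class MotifHit:
    """A scored, stranded motif occurrence.  The interval is always in
    forward-strand coordinates and has the matrix width."""

    interval: GenomicInterval
    score: float
    pwm_id: str
    factor_class: str | None = None

    @property
    def strand(self) -> str:
        return self.interval.strand


def window_score(pwm: PWM, subseq: str, strand: str = "+") -> float | None:
    """Score one window of length W, or ``None`` if it contains any N.

    For ``strand='-'`` the reverse complement of *subseq* is scored.
    """
    if len(subseq) != pwm.width:
        raise ValueError(f"window length {len(subseq)} != matrix width {pwm.width}")
    if strand not in ("+", "-"):
        raise ValueError(f"strand must be '+' or '-', got {strand!r}")
    seq = subseq.upper()
    if strand == "-":
        seq = reverse_complement(seq)
    total = 0.0
    for j, base in enumerate(seq):
        if base == "N":
            return None
        try:
            total += pwm.matrix[BASE_INDEX[base], j]
        except KeyError:
            raise ValueError(
                f"character {base!r} outside A,C,G,T,N (reader should have "
                "normalized the sequence)") from None
    return total


def threshold_from_fraction(pwm: PWM, fraction: float,
                            convention: str = "max") -> float:
    """Absolute score threshold for a percent threshold.

    ``convention='max'`` (default): ``fraction * max_score`` — percent of
    the highest attainable score, the semantics a percentage ``min.score``
    carries when scanning probability matrices.
    ``convention='minmax'``: ``min_score + fraction * (max_score - min_score)``,
    available for sensitivity analysis.
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    if convention == "max":
        return fraction * pwm.max_score
    if convention == "minmax":
        return pwm.min_score + fraction * (pwm.max_score - pwm.min_score)
    raise ValueError(f"unknown threshold convention {convention!r}")


def log_odds(pwm: PWM, pseudocount: float = 0.01) -> PWM:
    """Log2-odds transform against a uniform background, shifted to be
    non-negative so the percent-of-max threshold machinery still applies.
    Optional; probability matrices are scored as-is by default."""
    p = pwm.matrix + pseudocount
    p = p / p.sum(axis=0)
    lo = np.log2(p / 0.25)
    return PWM(id=pwm.id, matrix=lo - lo.min(), factor_class=pwm.factor_class)


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integer codes A=0,C=1,G=2,T=3,N=4."""
    lut = np.full(256, 4, dtype=np.int8)
    for base, code in BASE_INDEX.items():
        lut[ord(base)] = code
    return lut[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _scores_one_strand(codes: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Vectorized window scores at every start; NaN where a window holds an N."""
    W = matrix.shape[1]
    L = codes.size
    n_windows = L - W + 1
    if n_windows <= 0:
        return np.empty(0)
    # pad the weight table with a NaN row so code 4 (N) poisons the sum
    table = np.vstack([matrix, np.full((1, W), np.nan)])
    scores = np.zeros(n_windows)
    for j in range(W):
        scores += table[codes[j:j + n_windows], j]
    return scores


def scan_sequence(genome: dict, pwm: PWM, min_score_fraction: float = 0.80,
                  strands: str = "both", convention: str = "max") -> list:
    """Scan every chromosome of *genome* with *pwm*, retaining windows whose
    score is >= ``min_score_fraction`` of the matrix maximum (see
    :func:`threshold_from_fraction` for the convention).

    Returns hits sorted by (chrom, start, strand); coordinates always
    refer to the forward strand.  A matrix wider than every chromosome
    yields an empty result with a warning, not an error.
    """
    if strands not in ("forward", "both"):
        raise ValueError(f"strands must be 'forward' or 'both', got {strands!r}")
    threshold = threshold_from_fraction(pwm, min_score_fraction, convention)
    W = pwm.width
    hits: list[MotifHit] = []
    any_window = False
    matrices = [("+", pwm.matrix)]
    if strands == "both":
        matrices.append(("-", pwm.reverse_complement().matrix))
    for chrom in sorted(genome):
        seq = genome[chrom]
        if len(seq) < W:
            continue
        any_window = True
        codes = _encode(seq)
        for strand, matrix in matrices:
            scores = _scores_one_strand(codes, matrix)
            with np.errstate(invalid="ignore"):
                keep = np.nonzero(scores >= threshold)[0]
            for start in keep:
                hits.append(MotifHit(
                    interval=GenomicInterval(chrom, int(start), int(start) + W,
                                             name=pwm.id, strand=strand),
                    score=float(scores[start]),
                    pwm_id=pwm.id,
                    factor_class=pwm.factor_class,
                ))
    if not any_window:
        logger.warning("matrix %s (width %d) is wider than every chromosome; "
                       "no windows scanned", pwm.id, W)
    hits.sort(key=lambda h: (h.interval.chrom, h.interval.start, h.interval.strand))
    return hits


def hits_to_intervals(hits) -> list:
    """BED6-ready intervals for a hit list (name = matrix id, score = raw
    window score)."""
    return [GenomicInterval(h.interval.chrom, h.interval.start, h.interval.end,
                            name=h.pwm_id, score=h.score, strand=h.interval.strand)
            for h in hits]
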