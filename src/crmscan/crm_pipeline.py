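"""Candidate cis-regulatory module (CRM) inference.

An anchor peak set (Dll ChIP by default) is filtered through a sequence
of intersection requirements, always keeping the anchor peak's own
coordinates:

1. overlap with each required peak set (Sp1 ChIP, FAIRE accessibility),
   at a per-step overlap fraction (default: any overlap, >=1 bp);
2. full containment of at least one above-threshold motif hit per
   required factor class (Dll, Sp1, Pan, Mad by default), at a per-step
   containment fraction (default 1.0: the whole hit inside the peak);
3. nearest-transcript annotation of the survivors.

The *full logic* requires Sp1 evidence at both the peak and the motif
level; the *relaxed logic* drops both Sp1 requirements and is by
construction a superset of the full logic on identical inputs.  Multiple
matrices configured for one factor class are OR-combined: any full hit
from any matrix of the class satisfies the class.

Every filtering step logs input count, output count and the requirement
applied, so the funnel is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

from . import __version__
from .formats_io import (GenomicInterval, PWM, Transcript, as_interval,
                         check_chromosome_universe, write_bed)
from .interval_ops import ANY_OVERLAP, intersect_report_a, nearest_transcript
from .pwm_scan import MotifHit, scan_sequence

logger = logging.getLogger("crmscan")

FULL_MOTIF_CLASSES = ("dll", "sp1", "pan", "mad")
RELAXED_MOTIF_CLASSES = ("dll", "pan", "mad")


@dataclass(frozen=True)
class CriteriaConfig:
    """Which evidence a candidate must carry, and at what stringency.

    ``peak_requirements`` maps a peak-set name to the minimum overlap
    fraction of the *B* (required) peak; ``motif_requirements`` maps a
    factor class to its scan threshold (``min_score_fraction``) and
    containment fraction (``min_b_fraction``, anchored on the hit).
    """

    anchor: str = "dll_chip"
    peak_requirements: Mapping[str, float] = field(
        default_factory=lambda: {"sp1_chip": ANY_OVERLAP, "faire": ANY_OVERLAP})
    motif_requirements: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: {
            cls: {"min_score_fraction": 0.80, "min_b_fraction": 1.0}
            for cls in FULL_MOTIF_CLASSES})
    strands: str = "both"
    threshold_convention: str = "max"

    def __post_init__(self):
        if self.anchor in self.peak_requirements:
            raise ValueError(f"anchor {self.anchor!r} cannot also be a "
                             "peak requirement")
        if not self.motif_requirements:
            raise ValueError("motif_requirements must be non-empty")

    def without(self, requirement: str) -> "CriteriaConfig":
        """A copy with one named requirement removed (a peak-set name or a
        motif factor class)."""
        peaks = dict(self.peak_requirements)
        motifs = {k: dict(v) for k, v in self.motif_requirements.items()}
        if requirement in peaks:
            del peaks[requirement]
        elif requirement in motifs:
            del motifs[requirement]
        else:
            raise KeyError(f"no requirement named {requirement!r}")
        return replace(self, peak_requirements=peaks, motif_requirements=motifs)

    @property
    def requirement_names(self) -> tuple:
        return tuple(self.peak_requirements) + tuple(self.motif_requirements)


def relaxed_config(config: CriteriaConfig | None = None) -> CriteriaConfig:
    """The Sp1-excluded variant of *config*: both the Sp1 peak requirement
    and the Sp1 motif requirement are removed."""
    cfg = config or CriteriaConfig()
    for req in ("sp1_chip", "sp1"):
        if req in cfg.peak_requirements or req in cfg.motif_requirements:
            cfg = cfg.without(req)
    return cfg


@dataclass(frozen=True)
class CandidateCRM:
    """An anchor peak that survived every configured requirement."""

    interval: GenomicInterval              # anchor-peak coordinates, verbatim
    evidence: Mapping[str, int]            # factor class -> contained-hit count
    peak_support: tuple                    # required peak sets that overlapped
    nearest_gene: str | None
    nearest_transcript_id: str | None
    distance: int | None


def _contained_hit_counts(peak_iv: GenomicInterval, hits: Sequence[MotifHit],
                          min_b_fraction: float) -> int:
    n = 0
    for h in hits:
        iv = h.interval
        if iv.chrom != peak_iv.chrom:
            continue
        overlap = min(peak_iv.end, iv.end) - max(peak_iv.start, iv.start)
        if overlap >= 1 and overlap >= min_b_fraction * iv.length:
            n += 1
    return n


def run_pipeline(genome: dict, peaks: Mapping[str, Sequence],
                 pwms: Mapping[str, Sequence[PWM]],
                 transcripts: Sequence[Transcript],
                 config: CriteriaConfig | None = None) -> list:
    """Run the sequential intersection under *config* and return annotated
    :class:`CandidateCRM` records sorted by (chrom, start).

    *peaks* maps source name -> peak records (the anchor set plus every
    required set); *pwms* maps factor class -> one or more matrices
    (OR-combined within a class).  All inputs must share the genome's
    chromosome universe.
    """
    config = config or CriteriaConfig()

    if config.anchor not in peaks:
        raise ValueError(f"missing anchor peak set {config.anchor!r}")
    for req in config.peak_requirements:
        if req not in peaks:
            raise ValueError(f"missing required peak set {req!r}")
    for cls in config.motif_requirements:
        if cls not in pwms or not pwms[cls]:
            raise ValueError(f"no PWM configured for required motif class {cls!r}")

    for name, records in peaks.items():
        check_chromosome_universe(genome, (as_interval(r) for r in records),
                                  what=f"{name} peaks")
    check_chromosome_universe(genome, (t.interval for t in transcripts),
                              what="transcripts")

    survivors = list(peaks[config.anchor])
    logger.info("anchor %s: %d peaks", config.anchor, len(survivors))

    # step 1: peak-overlap requirements, anchor coordinates kept throughout
    for req, fraction in config.peak_requirements.items():
        before = len(survivors)
        survivors = intersect_report_a(survivors, peaks[req], fraction)
        logger.info("require %s overlap (fraction %g): %d -> %d",
                    req, fraction, before, len(survivors))

    # step 2: sequential motif-containment requirements
    hit_sets: dict[str, list[MotifHit]] = {}
    for cls, params in config.motif_requirements.items():
        cls_hits: list[MotifHit] = []
        for pwm in pwms[cls]:
            cls_hits.extend(scan_sequence(
                genome, pwm,
                min_score_fraction=params.get("min_score_fraction", 0.80),
                strands=config.strands,
                convention=config.threshold_convention))
        hit_sets[cls] = cls_hits
        before = len(survivors)
        survivors = intersect_report_a(
            survivors, cls_hits, params.get("min_b_fraction", 1.0))
        logger.info("require %s motif (%d hits genome-wide): %d -> %d",
                    cls, len(cls_hits), before, len(survivors))

    # step 3: evidence counts and nearest-transcript annotation
    candidates = []
    for rec in survivors:
        iv = as_interval(rec)
        evidence = {
            cls: _contained_hit_counts(iv, hit_sets[cls],
                                       params.get("min_b_fraction", 1.0))
            for cls, params in config.motif_requirements.items()}
        if transcripts:
            t, dist = nearest_transcript(iv, transcripts)
        else:
            t, dist = None, None
        candidates.append(CandidateCRM(
            interval=iv,
            evidence=evidence,
            peak_support=tuple(config.peak_requirements),
            nearest_gene=t.gene_id if t else None,
            nearest_transcript_id=t.transcript_id if t else None,
            distance=dist,
        ))
    candidates.sort(key=lambda c: (c.interval.chrom, c.interval.start,
                                   c.interval.end))
    logger.info("%d candidate CRMs", len(candidates))
    return candidates


def run_full_logic(genome, peaks, pwms, transcripts,
                   config: CriteriaConfig | None = None) -> list:
    """Full criteria set: Dll anchor, Sp1 + FAIRE peak overlap, and full
    containment of Dll, Sp1, Pan and Mad motif hits."""
    return run_pipeline(genome, peaks, pwms, transcripts,
                        config or CriteriaConfig())


def run_relaxed_logic(genome, peaks, pwms, transcripts,
                      config: CriteriaConfig | None = None) -> list:
    """Sp1-excluded criteria set (both the Sp1 peak and the Sp1 motif
    requirement dropped); a superset of the full logic by construction."""
    return run_pipeline(genome, peaks, pwms, transcripts,
                        relaxed_config(config))


# ---------------------------------------------------------------------------
# Reporting
# ---------------------------------------------------------------------------

def _digest(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def write_report(candidates: Sequence[CandidateCRM], path_prefix,
                 config: CriteriaConfig | None = None,
                 input_paths: Mapping[str, str] | None = None) -> dict:
    """Write ``<prefix>.tsv`` (full table), ``<prefix>.bed`` (BED6) and
    ``<prefix>.meta.json`` (config echo, input digests, version).

    The TSV carries chrom, start, end, nearest gene/transcript, distance,
    one ``n_<class>_hits`` count column per required class, and the
    peak-support flags.  Field formatting is deterministic, so two runs
    on identical inputs produce byte-identical files.
    """
    path_prefix = Path(path_prefix)
    path_prefix.parent.mkdir(parents=True, exist_ok=True)
    classes = sorted({cls for c in candidates for cls in c.evidence})
    if not classes and config is not None:
        classes = sorted(config.motif_requirements)
    supports = sorted({s for c in candidates for s in c.peak_support})
    if not supports and config is not None:
        supports = sorted(config.peak_requirements)

    tsv = path_prefix.with_suffix(".tsv")
    with open(tsv, "w") as fh:
        header = (["chrom", "start", "end", "gene_id", "transcript_id",
                   "distance"]
                  + [f"n_{cls}_hits" for cls in classes]
                  + [f"{s}_support" for s in supports])
        fh.write("\t".join(header) + "\n")
        for c in candidates:
            row = [c.interval.chrom, str(c.interval.start), str(c.interval.end),
                   c.nearest_gene or ".", c.nearest_transcript_id or ".",
                   "." if c.distance is None else str(c.distance)]
            row += [str(c.evidence.get(cls, 0)) for cls in classes]
            row += ["1" if s in c.peak_support else "0" for s in supports]
            fh.write("\t".join(row) + "\n")

    bed = path_prefix.with_suffix(".bed")
    write_bed([GenomicInterval(c.interval.chrom, c.interval.start, c.interval.end,
                               name=c.nearest_gene or ".",
                               score=None, strand=".")
               for c in candidates], bed)

    meta = {
        "version": __version__,
        "n_candidates": len(candidates),
        "config": _config_to_dict(config) if config else None,
        "inputs": {name: {"path": str(p), "sha256_16": _digest(p)}
                   for name, p in (input_paths or {}).items()},
    }
    meta_path = path_prefix.parent / (path_prefix.name + ".meta.json")
    meta_path.write_text(json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return {"tsv": tsv, "bed": bed, "meta": meta_path}


def _config_to_dict(config: CriteriaConfig) -> dict:
    return {
        "anchor": config.anchor,
        "peak_requirements": dict(config.peak_requirements),
        "motif_requirements": {k: dict(v)
                               for k, v in config.motif_requirements.items()},
        "strands": config.strands,
        "threshold_convention": config.threshold_convention,
    }


def read_report_tsv(path):
    """Re-read a report TSV into a pandas DataFrame (lossless for the
    listed columns)."""
    import pandas as pd
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})
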