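"""Seeded synthetic benchmark with known ground truth.

Emulates the structure of the real inputs — a multi-chromosome genome,
three partially overlapping peak sets (Dll ChIP, Sp1 ChIP, FAIRE), one
PWM per factor class, and a transcript map — with every planted region's
status known, so pipeline recovery can be scored without any external
data.

Regions come in two kinds:

* **true CRMs** satisfy all conditions by construction: their interval
  appears in all three peak files and carries one exact-consensus
  instance of every factor class, fully inside the peak;
* **decoys** realize a named condition-failure pattern — a missing peak
  file entry, a missing motif class, a Dll anchor absent from the Dll
  file, or a Dll motif straddling the peak edge by 1 bp (present, but
  not fully contained).

Decoy regions whose pattern requires a motif class to be *absent* are
scrubbed: background windows of that class scoring at or above the scrub
threshold (default 0.8 of the matrix maximum, the pipeline's default
scan fraction) are mutated away, so the decoy fails exactly the
condition its pattern names.  Pipelines run below the scrub fraction
void that guarantee.

The background is i.i.d. at a configurable GC content (no Markov
structure); a single :class:`numpy.random.Generator` seeded from
``SimulationConfig.seed`` drives every draw, so two runs with one seed
produce byte-identical corpora.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .formats_io import (BASE_INDEX, BASE_ORDER, GenomicInterval, PWM,
                         Transcript, as_interval, write_bed, write_fasta,
                         write_pwm_jaspar, write_transcripts_bed)
from .interval_ops import nearest_transcript
from .pwm_scan import reverse_complement, window_score

logger = logging.getLogger("crmscan")

#: The seven logical conditions a region may satisfy, in mask order:
#: membership in each peak file, then full containment of each motif class.
CONDITIONS = ("dll_chip", "sp1_chip", "faire", "dll", "sp1", "pan", "mad")
MOTIF_CLASSES = ("dll", "sp1", "pan", "mad")
PEAK_FILES = ("dll_chip", "sp1_chip", "faire")


@dataclass(frozen=True)
class DecoyPattern:
    """One engineered failure mode: *failed_condition* names the single
    condition the decoy does not satisfy.  ``straddle=True`` means the
    motif is present but crosses the peak edge by 1 bp instead of being
    absent — it probes containment semantics rather than motif presence."""

    name: str
    failed_condition: str
    straddle: bool = False

    @property
    def mask(self) -> str:
        """7-bit satisfaction mask over :data:`CONDITIONS` (1 = satisfied)."""
        return "".join("0" if c == self.failed_condition else "1"
                       for c in CONDITIONS)


DEFAULT_DECOY_PATTERNS = tuple(
    [DecoyPattern(f"no_{c}", c) for c in CONDITIONS]
    + [DecoyPattern("straddle_dll", "dll", straddle=True)]
)


@dataclass(frozen=True)
class PwmSpec:
    width: int
    sharpness: float = 0.9   # probability mass on the consensus base

    def __post_init__(self):
        if self.width < 1:
            raise ValueError("PWM width must be >= 1")
        if not (0.25 < self.sharpness <= 1.0):
            raise ValueError("sharpness must lie in (0.25, 1]")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 50_000
    gc_content: float = 0.42
    pwm_specs: Mapping[str, PwmSpec] = field(default_factory=lambda: {
        "dll": PwmSpec(8), "sp1": PwmSpec(10), "pan": PwmSpec(9),
        "mad": PwmSpec(6)})
    n_true_crms: int = 12
    n_decoys_per_pattern: int = 2
    decoy_patterns: Sequence[DecoyPattern] = DEFAULT_DECOY_PATTERNS
    peak_width_min: int = 200
    peak_width_max: int = 400
    n_transcripts: int = 30
    peak_jitter_bp: int = 0   # outward edge jitter for the Sp1/FAIRE copies
    scrub_fraction: float = 0.80
    #: draw planted instance bases from the PWM columns instead of writing
    #: the exact consensus — instances then score below the maximum at
    #: sharpness < 1, for graded-degradation experiments
    sample_instances: bool = False

    def __post_init__(self):
        if self.n_true_crms < 0 or self.n_decoys_per_pattern < 0:
            raise ValueError("counts must be >= 0")
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must lie in (0, 1)")
        if not (1 <= self.peak_width_min <= self.peak_width_max):
            raise ValueError("need 1 <= peak_width_min <= peak_width_max")
        missing = set(MOTIF_CLASSES) - set(self.pwm_specs)
        if missing:
            raise ValueError(f"pwm_specs missing classes: {sorted(missing)}")


@dataclass(frozen=True)
class PlantedHit:
    interval: GenomicInterval
    factor_class: str
    strand: str
    region_name: str


@dataclass
class SyntheticTruth:
    """Ground-truth ledger the recovery evaluation is scored against."""

    true_crms: list                       # anchor-peak intervals, all satisfied
    decoys: dict                          # pattern name -> list of intervals
    patterns: dict                        # pattern name -> DecoyPattern
    planted_hits: list                    # PlantedHit records
    transcript_assignments: dict          # true-CRM name -> (gene_id, distance)

    def decoy_mask(self, pattern_name: str) -> str:
        return self.patterns[pattern_name].mask


@dataclass
class SyntheticDataset:
    genome: dict
    peaks: dict                            # source -> list of GenomicInterval
    pwms: dict                             # class -> [PWM]
    transcripts: list
    truth: SyntheticTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------

def _base_probs(gc: float) -> np.ndarray:
    return np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> list:
    return list(rng.choice(list(BASE_ORDER), size=length, p=_base_probs(gc)))


def _make_pwm(cls: str, consensus: str, sharpness: float) -> PWM:
    w = len(consensus)
    off = (1.0 - sharpness) / 3.0
    m = np.full((4, w), off)
    for j, base in enumerate(consensus):
        m[BASE_INDEX[base], j] = sharpness
    return PWM(id=f"{cls}_syn", matrix=m, factor_class=cls)


def _draw_consensi(rng: np.random.Generator, config: SimulationConfig) -> dict:
    """Random consensus strings, redrawn until no consensus contains a
    window (either strand) scoring >= the scrub threshold under another
    class's matrix — otherwise a planted instance of one class could
    irreparably fake a hit of a scrubbed class."""
    for _ in range(200):
        consensi = {cls: "".join(rng.choice(list(BASE_ORDER),
                                            size=spec.width))
                    for cls, spec in config.pwm_specs.items()}
        pwms = {cls: _make_pwm(cls, cons, config.pwm_specs[cls].sharpness)
                for cls, cons in consensi.items()}
        if not _consensi_conflict(consensi, pwms, config.scrub_fraction):
            return consensi
    raise RuntimeError("could not draw a conflict-free consensus set; "
                       "widths may be too similar or too short")


def _consensi_conflict(consensi: dict, pwms: dict, fraction: float) -> bool:
    """True when some alignment of a probe class's matrix against a planted
    instance of any class (either orientation, any offset, including full
    containment) could stay at or above the scrub threshold even with every
    non-instance base set to the probe's column minimum.  Such a consensus
    set would make decoy scrubbing infeasible, so the generator redraws it.
    """
    for host_cls, host_cons in consensi.items():
        for host_seq in (host_cons, reverse_complement(host_cons)):
            for probe_cls, pwm in pwms.items():
                thr = fraction * pwm.max_score
                W = pwm.width
                H = len(host_seq)
                for matrix in (pwm.matrix, pwm.reverse_complement().matrix):
                    col_min = matrix.min(axis=0)
                    for t in range(-(W - 1), H):
                        overlap = min(H, t + W) - max(0, t)
                        if overlap <= 0:
                            continue
                        if probe_cls == host_cls and overlap == W:
                            continue  # the planted instance itself
                        score = 0.0
                        for j in range(W):
                            if 0 <= t + j < H:
                                score += matrix[BASE_INDEX[host_seq[t + j]], j]
                            else:
                                score += col_min[j]
                        if score >= thr:
                            return True
    return False


# ---------------------------------------------------------------------------
# region layout
# ---------------------------------------------------------------------------

def _layout_regions(rng, config: SimulationConfig, n_regions: int,
                    margin: int) -> list:
    """Non-overlapping (chrom, peak_start, peak_width) slots; errors when
    they cannot fit."""
    span = config.peak_width_max + 2 * margin
    slots = []
    for ci in range(config.n_chroms):
        chrom = f"chr{ci + 1}"
        for si in range(config.chrom_length // span):
            slots.append((chrom, si * span))
    if n_regions > len(slots):
        raise ValueError(
            f"cannot place {n_regions} non-overlapping regions of span {span} bp "
            f"in {config.n_chroms} x {config.chrom_length} bp; use larger "
            "chromosomes or fewer regions")
    chosen = rng.choice(len(slots), size=n_regions, replace=False)
    out = []
    for idx in chosen:
        chrom, slot_start = slots[idx]
        width = int(rng.integers(config.peak_width_min,
                                 config.peak_width_max + 1))
        wiggle = config.peak_width_max - width
        start = slot_start + margin + int(rng.integers(0, wiggle + 1))
        out.append((chrom, start, width))
    return out


def _plant_offsets(rng, peak_width: int, widths: Sequence[int],
                   gap: int) -> list:
    """Start offsets (within the peak) for instances of the given widths,
    in order, separated by at least *gap* bp."""
    k = len(widths)
    needed = sum(widths) + (k - 1) * gap if k else 0
    slack = peak_width - needed
    if slack < 0:
        raise ValueError("peak too narrow for the requested plantings")
    parts = rng.multinomial(slack, [1.0 / (k + 1)] * (k + 1)) if k else []
    offsets, cursor = [], 0
    for i, w in enumerate(widths):
        cursor += int(parts[i])
        offsets.append(cursor)
        cursor += w + gap
    return offsets


# ---------------------------------------------------------------------------
# scrubbing
# ---------------------------------------------------------------------------

def _window_scores_both(seq_chars: Sequence[str], start: int, pwm: PWM):
    window = "".join(seq_chars[start:start + pwm.width])
    return (window_score(pwm, window, "+"), window_score(pwm, window, "-"))


def _scrub_span(seq: list, protected: set, span_start: int, span_end: int,
                pwm: PWM, threshold: float, rng: np.random.Generator,
                budget: int = 2000) -> None:
    """Mutate unprotected bases until no window fully inside
    [span_start, span_end) scores >= *threshold* on either strand.

    A window always has an unprotected position because planted instances
    are spaced further apart than any matrix width and within-instance
    windows are excluded by the consensus screening.  Positions and
    replacement bases are drawn from the seeded generator: overlapping
    offender windows share positions, and a deterministic fix-up rule can
    flip a shared base back and forth indefinitely.
    """
    W = pwm.width
    for _ in range(budget):
        offender = None
        for s in range(span_start, span_end - W + 1):
            fwd, rev = _window_scores_both(seq, s, pwm)
            if (fwd is not None and fwd >= threshold) or \
               (rev is not None and rev >= threshold):
                offender = s
                break
        if offender is None:
            return
        free = [p for p in range(offender, offender + W) if p not in protected]
        if not free:
            raise RuntimeError("scrub window fully protected; planted "
                               "instances too dense")
        for idx in rng.permutation(len(free)):
            p = free[int(idx)]
            vals = {}
            original = seq[p]
            for base in BASE_ORDER:
                seq[p] = base
                fwd, rev = _window_scores_both(seq, offender, pwm)
                vals[base] = max(fwd if fwd is not None else -np.inf,
                                 rev if rev is not None else -np.inf)
            seq[p] = original
            below = [b for b in BASE_ORDER if vals[b] < threshold]
            if below:
                seq[p] = below[int(rng.integers(len(below)))]
                break
            # no single-base fix at this position: keep the best and continue
            seq[p] = min(BASE_ORDER, key=vals.get)
    else:
        raise RuntimeError("scrub budget exhausted; try a different seed or "
                           "larger chromosomes")


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------

def simulate(config: SimulationConfig, outdir=None) -> SyntheticDataset:
    """Generate a seeded synthetic corpus; optionally serialize it under
    *outdir* using the package's own format writers.

    Returns the in-memory dataset (genome, peak sets, PWMs, transcripts,
    truth ledger).  Deterministic given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)

    consensi = _draw_consensi(rng, config)
    pwms = {cls: _make_pwm(cls, consensi[cls],
                           config.pwm_specs[cls].sharpness)
            for cls in MOTIF_CLASSES}
    max_w = max(p.width for p in pwms.values())
    inter_gap = max_w  # no window can span two planted instances

    # background genome as mutable per-chromosome character lists
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    seqs = {c: _random_seq(rng, config.chrom_length, config.gc_content)
            for c in chroms}

    patterns = list(config.decoy_patterns)
    jobs = ([("true", None)] * config.n_true_crms
            + [("decoy", pat) for pat in patterns
               for _ in range(config.n_decoys_per_pattern)])
    margin = 2 * max_w + config.peak_jitter_bp + 10
    layout = _layout_regions(rng, config, len(jobs), margin)

    peak_files: dict[str, list] = {src: [] for src in PEAK_FILES}
    true_crms: list[GenomicInterval] = []
    decoys: dict[str, list] = {pat.name: [] for pat in patterns}
    planted: list[PlantedHit] = []
    counters = {"true": 0, **{pat.name: 0 for pat in patterns}}

    for (kind, pat), (chrom, start, width) in zip(jobs, layout):
        seq = seqs[chrom]
        end = start + width
        if kind == "true":
            counters["true"] += 1
            name = f"crm_{counters['true']:03d}"
            absent_classes, straddle_cls, in_files = [], None, set(PEAK_FILES)
        else:
            counters[pat.name] += 1
            name = f"decoy_{pat.name}_{counters[pat.name]:02d}"
            in_files = set(PEAK_FILES)
            absent_classes, straddle_cls = [], None
            if pat.failed_condition in PEAK_FILES:
                in_files.discard(pat.failed_condition)
            elif pat.straddle:
                straddle_cls = pat.failed_condition
            else:
                absent_classes = [pat.failed_condition]

        plant_classes = [c for c in MOTIF_CLASSES
                         if c not in absent_classes and c != straddle_cls]
        # reserve the left end of the peak when an instance straddles it
        base_off = (pwms[straddle_cls].width - 1 + inter_gap
                    if straddle_cls is not None else 0)
        offsets = [base_off + o for o in _plant_offsets(
            rng, width - base_off,
            [pwms[c].width for c in plant_classes], inter_gap)]
        protected: set[int] = set()
        placements = list(zip(plant_classes, offsets))
        if straddle_cls is not None:
            # instance overhangs the left peak edge by exactly 1 bp
            placements.append((straddle_cls, -1))
        for cls, off in placements:
            inst_start = start + off
            if config.sample_instances:
                cols = pwms[cls].matrix
                cons = "".join(
                    BASE_ORDER[int(rng.choice(4, p=cols[:, j] / cols[:, j].sum()))]
                    for j in range(cols.shape[1]))
            else:
                cons = consensi[cls]
            strand = "+" if rng.random() < 0.5 else "-"
            planted_seq = cons if strand == "+" else reverse_complement(cons)
            for j, base in enumerate(planted_seq):
                seq[inst_start + j] = base
                protected.add(inst_start + j)
            planted.append(PlantedHit(
                interval=GenomicInterval(chrom, inst_start,
                                         inst_start + len(cons),
                                         name=f"{cls}_syn", strand=strand),
                factor_class=cls, strand=strand, region_name=name))

        scrub_classes = list(absent_classes)
        if straddle_cls is not None:
            scrub_classes.append(straddle_cls)  # no second, contained instance
        for cls in scrub_classes:
            _scrub_span(seq, protected, start, end, pwms[cls],
                        config.scrub_fraction * pwms[cls].max_score, rng)

        anchor = GenomicInterval(chrom, start, end, name=name)
        if kind == "true":
            true_crms.append(anchor)
        else:
            decoys[pat.name].append(anchor)
        for src in PEAK_FILES:
            if src not in in_files:
                continue
            if src == "dll_chip" or config.peak_jitter_bp == 0:
                peak_files[src].append(anchor)
            else:
                lo = max(0, start - int(rng.integers(0, config.peak_jitter_bp + 1)))
                hi = min(config.chrom_length,
                         end + int(rng.integers(0, config.peak_jitter_bp + 1)))
                peak_files[src].append(GenomicInterval(chrom, lo, hi, name=name))

    genome = {c: "".join(seqs[c]) for c in chroms}
    for src in peak_files:
        peak_files[src].sort(key=lambda iv: (iv.chrom, iv.start, iv.end))

    transcripts = _make_transcripts(rng, config, chroms)
    assignments = {}
    for crm in true_crms:
        if transcripts:
            t, d = nearest_transcript(crm, transcripts)
            if t is not None:
                assignments[crm.name] = (t.gene_id, d)

    truth = SyntheticTruth(
        true_crms=true_crms, decoys=decoys,
        patterns={pat.name: pat for pat in patterns},
        planted_hits=planted, transcript_assignments=assignments)
    dataset = SyntheticDataset(genome=genome, peaks=peak_files, pwms={
        cls: [pwm] for cls, pwm in pwms.items()},
        transcripts=transcripts, truth=truth, config=config)

    if outdir is not None:
        write_dataset(dataset, outdir)
    return dataset


def _make_transcripts(rng, config: SimulationConfig, chroms) -> list:
    out = []
    for i in range(config.n_transcripts):
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        width = int(rng.integers(500, 3001))
        width = min(width, config.chrom_length - 1)
        start = int(rng.integers(0, config.chrom_length - width))
        strand = "+" if rng.random() < 0.5 else "-"
        out.append(Transcript(
            interval=GenomicInterval(chrom, start, start + width,
                                     strand=strand),
            transcript_id=f"tx_{i + 1:04d}", gene_id=f"gene_{i + 1:04d}"))
    return out


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> dict:
    """Serialize genome, peak BEDs, PWMs, transcripts and the truth ledger
    under *outdir*; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"genome": outdir / "genome.fa",
             "transcripts": outdir / "transcripts.bed",
             "truth": outdir / "truth.tsv",
             "planted_hits": outdir / "planted_hits.tsv"}
    write_fasta(dataset.genome, paths["genome"])
    for src, records in dataset.peaks.items():
        paths[src] = outdir / f"{src}.bed"
        write_bed(records, paths[src])
    for cls, pwm_list in dataset.pwms.items():
        paths[f"pwm_{cls}"] = outdir / f"pwm_{cls}.jaspar"
        write_pwm_jaspar(pwm_list[0], paths[f"pwm_{cls}"])
    write_transcripts_bed(dataset.transcripts, paths["transcripts"])
    write_truth(dataset.truth, paths["truth"], paths["planted_hits"])
    cfg = dataset.config
    (outdir / "config.json").write_text(json.dumps({
        "seed": cfg.seed, "n_chroms": cfg.n_chroms,
        "chrom_length": cfg.chrom_length, "gc_content": cfg.gc_content,
        "n_true_crms": cfg.n_true_crms,
        "n_decoys_per_pattern": cfg.n_decoys_per_pattern,
        "peak_width": [cfg.peak_width_min, cfg.peak_width_max],
        "n_transcripts": cfg.n_transcripts,
        "peak_jitter_bp": cfg.peak_jitter_bp,
        "scrub_fraction": cfg.scrub_fraction,
        "pwm_specs": {c: {"width": s.width, "sharpness": s.sharpness}
                      for c, s in cfg.pwm_specs.items()},
    }, indent=2, sort_keys=True) + "\n")
    return paths


def write_truth(truth: SyntheticTruth, truth_path, hits_path=None) -> None:
    """Truth ledger as a documented TSV: one row per region with its kind,
    failure pattern and 7-bit satisfaction mask; planted instances in a
    companion TSV."""
    with open(truth_path, "w") as fh:
        fh.write("# synthetic ground truth; mask bits over: "
                 + ",".join(CONDITIONS) + " (1 = satisfied)\n")
        fh.write("chrom\tstart\tend\tname\tkind\tpattern\tmask\t"
                 "nearest_gene\tdistance\n")
        for iv in truth.true_crms:
            gene, dist = truth.transcript_assignments.get(iv.name, (".", "."))
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\ttrue\t.\t"
                     f"{'1' * len(CONDITIONS)}\t{gene}\t{dist}\n")
        for pname in sorted(truth.decoys):
            for iv in truth.decoys[pname]:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\tdecoy\t"
                         f"{pname}\t{truth.decoy_mask(pname)}\t.\t.\n")
    if hits_path is not None:
        with open(hits_path, "w") as fh:
            fh.write("chrom\tstart\tend\tfactor_class\tstrand\tregion\n")
            for h in truth.planted_hits:
                fh.write(f"{h.interval.chrom}\t{h.interval.start}\t"
                         f"{h.interval.end}\t{h.factor_class}\t{h.strand}\t"
                         f"{h.region_name}\n")


def read_truth(truth_path) -> SyntheticTruth:
    """Re-load a serialized truth ledger (planted hits and transcript
    assignments are carried in the TSV columns that encode them)."""
    true_crms, decoys, patterns, assignments = [], {}, {}, {}
    with open(truth_path) as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("chrom\t"):
                continue
            (chrom, start, end, name, kind, pattern, mask,
             gene, dist) = line.rstrip("\n").split("\t")
            iv = GenomicInterval(chrom, int(start), int(end), name=name)
            if kind == "true":
                true_crms.append(iv)
                if gene != ".":
                    assignments[name] = (gene, int(dist))
            else:
                decoys.setdefault(pattern, []).append(iv)
                if pattern not in patterns:
                    failed = [c for c, bit in zip(CONDITIONS, mask)
                              if bit == "0"]
                    patterns[pattern] = DecoyPattern(
                        pattern, failed[0] if failed else "",
                        straddle="straddle" in pattern)
    return SyntheticTruth(true_crms=true_crms, decoys=decoys,
                          patterns=patterns, planted_hits=[],
                          transcript_assignments=assignments)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def evaluate_recovery(predicted, truth: SyntheticTruth) -> dict:
    """Score predictions against the truth's anchor-peak coordinates by
    interval identity.

    precision = TP/(TP+FP), defined as 1.0 when there are no predictions;
    recall = TP/(TP+FN), defined as 1.0 when there is no truth.
    """
    pred = {(as_interval(p).chrom, as_interval(p).start, as_interval(p).end)
            for p in predicted}
    true = {(iv.chrom, iv.start, iv.end) for iv in truth.true_crms}
    tp = len(pred & true)
    fp = len(pred - true)
    fn = len(true - pred)
    return {
        "true_positives": tp,
        "false_positives": fp,
        "false_negatives": fn,
        "precision": 1.0 if not pred else tp / (tp + fp),
        "recall": 1.0 if not true else tp / (tp + fn),
    }
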