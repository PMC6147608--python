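"""Readers and writers for the genomics formats the pipeline touches.

Everything downstream of this module speaks one coordinate convention:
0-based, half-open (BED-native).  GTF input (1-based, inclusive) is
converted on read.  Chromosome names are taken literally — no "chr"
aliasing — and a mismatch between the chromosome universes of a FASTA
and the interval files consumed against it is a hard error, because a
silently empty intersection is the classic failure mode of this kind of
pipeline.

Supported dialects:

* FASTA (multi-record; non-ACGT characters folded to ``N`` with a warning)
* BED6 and ENCODE narrowPeak (10-column)
* minimal GTF (``transcript`` feature rows only)
* PWM matrices: JASPAR single-matrix text, a minimal MEME motif block,
  and a bare 4-row TSV
"""

from __future__ import annotations

import logging

import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("crmscan")

#: Canonical row order of every PWM matrix in the package.
BASE_ORDER = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASE_ORDER)}

#: Sources a peak file may be labelled with.
PEAK_SOURCES = ("dll_chip", "sp1_chip", "faire")


class FormatError(ValueError):
    """A malformed input file; carries the offending path and line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A chromosome-anchored half-open coordinate span.

    ``start`` is 0-based inclusive, ``end`` 0-based exclusive, so
    ``len = end - start``.  The universal currency of peaks, motif hits
    and candidate CRMs.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Width of the coordinate overlap with *other* (0 if disjoint or
        on a different chromosome)."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class Peak:
    """A called peak: ChIP-seq binding event or FAIRE accessibility region."""

    interval: GenomicInterval
    source: str | None = None
    summit_offset: int | None = None
    signal: float | None = None
    p_score: float | None = None
    q_score: float | None = None

    def __post_init__(self):
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.interval.length
        ):
            raise ValueError(
                f"summit_offset {self.summit_offset} outside [0, {self.interval.length})"
            )


@dataclass(frozen=True)
class Transcript:
    interval: GenomicInterval
    transcript_id: str
    gene_id: str


@dataclass(frozen=True)
class PWM:
    """A position weight matrix: 4 x W non-negative weights, rows in
    A,C,G,T order.  Probabilities by default (each column sums to 1);
    arbitrary non-negative weights are allowed so a log-odds transform
    can reuse the type.
    """

    id: str
    matrix: np.ndarray
    factor_class: str | None = None

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[0] != 4 or m.shape[1] < 1:
            raise ValueError(f"PWM matrix must be 4 x W with W >= 1, got {m.shape}")
        if np.any(m < 0):
            raise ValueError("PWM matrix entries must be non-negative")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[1]

    @property
    def max_score(self) -> float:
        """Highest attainable window score: sum of column maxima."""
        return float(self.matrix.max(axis=0).sum())

    @property
    def min_score(self) -> float:
        return float(self.matrix.min(axis=0).sum())

    @property
    def consensus(self) -> str:
        """Highest-weight base per column (ties broken toward A<C<G<T)."""
        return "".join(BASE_ORDER[i] for i in self.matrix.argmax(axis=0))

    def reverse_complement(self) -> "PWM":
        return PWM(id=self.id, matrix=self.matrix[::-1, ::-1],
                   factor_class=self.factor_class)


#: Genome as a mapping chromosome name -> uppercase sequence over {A,C,G,T,N}.
GenomeSequence = dict


def check_chromosome_universe(genome: dict, intervals: Iterable[GenomicInterval],
                              what: str = "intervals") -> None:
    """Hard error if any interval names a chromosome absent from *genome*."""
    orphans = sorted({iv.chrom for iv in intervals} - set(genome))
    if orphans:
        raise ValueError(
            f"{what} reference chromosomes absent from the genome: "
            + ", ".join(orphans)
        )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

_NON_ACGTN = re.compile(r"[^ACGTN]")


def read_fasta(path) -> dict:
    """Read a (multi-record) FASTA into ``{chrom: sequence}``.

    Sequences are uppercased; characters outside {A,C,G,T,N} are mapped
    to ``N`` with a logged warning.  The chromosome name is the first
    whitespace-delimited token of the header line.
    """
    path = Path(path)
    genome: dict[str, str] = {}
    name: str | None = None
    chunks: list[str] = []
    n_folded = 0

    def _flush():
        nonlocal name, chunks
        if name is not None:
            genome[name] = "".join(chunks)
        chunks = []

    with open(path) as fh:
        seen_any = False
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            seen_any = True
            if line.startswith(">"):
                _flush()
                name = line[1:].split()[0] if line[1:].split() else ""
                if not name:
                    raise FormatError("empty FASTA header", path, lineno)
                if name in genome or name == "":
                    raise FormatError(f"duplicate chromosome {name!r}", path, lineno)
            else:
                if name is None:
                    raise FormatError("sequence data before any FASTA header",
                                      path, lineno)
                seq = line.upper()
                folded = _NON_ACGTN.subn("N", seq)
                n_folded += folded[1]
                chunks.append(folded[0])
        if not seen_any:
            raise FormatError("empty FASTA file", path, 1)
    _flush()
    if n_folded:
        logger.warning("%s: %d non-ACGT characters folded to N", path, n_folded)
    return genome


def write_fasta(genome: dict, path, line_width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), line_width):
                fh.write(seq[i:i + line_width] + "\n")


# ---------------------------------------------------------------------------
# BED / narrowPeak
# ---------------------------------------------------------------------------

def _parse_int(token: str, what: str, path, lineno: int) -> int:
    try:
        return int(token)
    except ValueError:
        raise FormatError(f"non-integer {what}: {token!r}", path, lineno) from None


def _parse_interval(fields: Sequence[str], path, lineno: int) -> GenomicInterval:
    chrom = fields[0]
    start = _parse_int(fields[1], "start", path, lineno)
    end = _parse_int(fields[2], "end", path, lineno)
    name = None
    score = None
    strand = "."
    if len(fields) > 3 and fields[3] != ".":
        name = fields[3]
    if len(fields) > 4 and fields[4] != ".":
        try:
            score = float(fields[4])
        except ValueError:
            raise FormatError(f"non-numeric score: {fields[4]!r}", path, lineno) from None
    if len(fields) > 5 and fields[5] != ".":
        strand = fields[5]
    try:
        return GenomicInterval(chrom, start, end, name=name, score=score, strand=strand)
    except ValueError as exc:
        raise FormatError(str(exc), path, lineno) from None


def read_bed(path, kind: str = "bed6", source: str | None = None):
    """Read a BED6 (``kind='bed6'``) or ENCODE narrowPeak (``kind='narrowpeak'``)
    file.

    BED6 rows yield :class:`GenomicInterval`; narrowPeak rows yield
    :class:`Peak` with the signal/p/q columns attached and the ENCODE
    ``-1`` summit sentinel mapped to an absent ``summit_offset``.
    Input order is preserved.
    """
    path = Path(path)
    if kind not in ("bed6", "narrowpeak"):
        raise ValueError(f"unknown BED kind {kind!r}")
    records = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if kind == "bed6":
                if len(fields) < 3:
                    raise FormatError(
                        f"expected >=3 tab-delimited columns, got {len(fields)}",
                        path, lineno)
                records.append(_parse_interval(fields[:6], path, lineno))
            else:
                if len(fields) != 10:
                    raise FormatError(
                        f"narrowPeak requires 10 columns, got {len(fields)}",
                        path, lineno)
                iv = _parse_interval(fields[:6], path, lineno)

                def _opt_float(tok):
                    if tok in (".", "-1", "-1.0"):
                        return None
                    return float(tok)

                summit = _parse_int(fields[9], "summit offset", path, lineno)
                try:
                    records.append(Peak(
                        interval=iv,
                        source=source,
                        summit_offset=None if summit == -1 else summit,
                        signal=_opt_float(fields[6]),
                        p_score=_opt_float(fields[7]),
                        q_score=_opt_float(fields[8]),
                    ))
                except ValueError as exc:
                    raise FormatError(str(exc), path, lineno) from None
    return records


def as_interval(record) -> GenomicInterval:
    """The :class:`GenomicInterval` of *record*, whatever wrapper it is in."""
    if isinstance(record, GenomicInterval):
        return record
    return record.interval


def write_bed(records, path, score_decimals: int = 4) -> None:
    """Write intervals (or peak/candidate records carrying one) as BED6.

    Field formatting is deterministic: scores are rendered with
    ``score_decimals`` decimal places, absent name/score as ``.``, so a
    round-trip through :func:`read_bed` is lossless for the fields BED6
    carries.
    """
    with open(path, "w") as fh:
        for rec in records:
            iv = as_interval(rec)
            score = "." if iv.score is None else f"{iv.score:.{score_decimals}f}"
            name = iv.name if iv.name is not None else "."
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Transcript annotation (BED or minimal GTF)
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_transcripts(path, kind: str = "bed"):
    """Read a transcript map as BED (first 6 columns; name = transcript id,
    ``gene_id`` defaulting to the transcript id unless given as
    ``gene_id|transcript_id``) or as minimal GTF (only ``transcript``
    feature rows; 1-based inclusive coordinates converted to 0-based
    half-open; ``gene_id`` and ``transcript_id`` attributes required).

    Duplicate transcript ids are a format error.
    """
    path = Path(path)
    out: list[Transcript] = []
    seen: dict[str, int] = {}
    warned_extra = False
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if kind == "bed":
                if len(fields) < 4:
                    raise FormatError("transcript BED needs >=4 columns", path, lineno)
                if len(fields) > 6 and not warned_extra:
                    logger.warning("%s: columns beyond 6 ignored", path)
                    warned_extra = True
                iv = _parse_interval(fields[:6], path, lineno)
                name = iv.name or ""
                if "|" in name:
                    gene_id, transcript_id = name.split("|", 1)
                else:
                    gene_id = transcript_id = name
                if not transcript_id:
                    raise FormatError("missing transcript name", path, lineno)
            elif kind == "gtf_minimal":
                if len(fields) != 9:
                    raise FormatError(f"GTF requires 9 columns, got {len(fields)}",
                                      path, lineno)
                if fields[2] != "transcript":
                    continue
                start1 = _parse_int(fields[3], "start", path, lineno)
                end1 = _parse_int(fields[4], "end", path, lineno)
                attrs = dict(_GTF_ATTR.findall(fields[8]))
                for req in ("gene_id", "transcript_id"):
                    if req not in attrs:
                        raise FormatError(f"missing required attribute {req}",
                                          path, lineno)
                strand = fields[6] if fields[6] in ("+", "-") else "."
                try:
                    iv = GenomicInterval(fields[0], start1 - 1, end1,
                                         name=attrs["transcript_id"], strand=strand)
                except ValueError as exc:
                    raise FormatError(str(exc), path, lineno) from None
                gene_id, transcript_id = attrs["gene_id"], attrs["transcript_id"]
            else:
                raise ValueError(f"unknown transcript kind {kind!r}")
            if transcript_id in seen:
                raise FormatError(
                    f"duplicate transcript_id {transcript_id!r} "
                    f"(first seen at line {seen[transcript_id]})", path, lineno)
            seen[transcript_id] = lineno
            out.append(Transcript(interval=iv, transcript_id=transcript_id,
                                  gene_id=gene_id))
    return out


def write_transcripts_bed(transcripts: Sequence[Transcript], path) -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            name = (t.transcript_id if t.gene_id == t.transcript_id
                    else f"{t.gene_id}|{t.transcript_id}")
            fh.write(f"{t.interval.chrom}\t{t.interval.start}\t{t.interval.end}"
                     f"\t{name}\t.\t{t.interval.strand}\n")


# ---------------------------------------------------------------------------
# PWM dialects
# ---------------------------------------------------------------------------

def _normalize_matrix(rows: dict, path, lineno: int | None = None) -> np.ndarray:
    """Validate a 4-row matrix keyed by base and return column-normalized
    probabilities.  Accepts count-like columns (normalized by their sum)
    or probability-like columns (each sum within 1e-6 of 1)."""
    widths = {len(v) for v in rows.values()}
    if set(rows) != set(BASE_ORDER):
        raise FormatError(f"matrix rows must cover A,C,G,T, got {sorted(rows)}",
                          path, lineno)
    if len(widths) != 1:
        raise FormatError(f"ragged matrix rows, widths {sorted(widths)}", path, lineno)
    m = np.array([rows[b] for b in BASE_ORDER], dtype=float)
    if m.shape[1] < 1:
        raise FormatError("matrix must have at least one column", path, lineno)
    if np.any(m < 0):
        raise FormatError("negative matrix entries", path, lineno)
    sums = m.sum(axis=0)
    if np.any(sums == 0):
        raise FormatError("matrix column sums to zero", path, lineno)
    if np.allclose(sums, 1.0, atol=1e-6):
        return m
    # count-like: positive sums, normalize each column
    return m / sums


def read_pwm(path, dialect: str = "jaspar", factor_class: str | None = None) -> PWM:
    """Read one PWM.  Dialects:

    ``jaspar``
        ``>ID name`` header, then 4 rows ``A  [ 8  0 ... ]`` (brackets
        optional), in any base order.
    ``meme_minimal``
        a ``MOTIF <id>`` line followed by a ``letter-probability matrix``
        block whose rows are columns of the PWM in A,C,G,T order.
    ``tsv``
        4 tab/space-separated numeric rows in A,C,G,T order; an optional
        leading base label per row; optional ``#``/``>`` header giving the id.

    Counts are column-normalized to probabilities; probability matrices
    are accepted if each column sums to 1 +/- 1e-6.
    """
    path = Path(path)
    text = Path(path).read_text()
    if dialect == "jaspar":
        return _read_pwm_jaspar(text, path, factor_class)
    if dialect == "meme_minimal":
        return _read_pwm_meme(text, path, factor_class)
    if dialect == "tsv":
        return _read_pwm_tsv(text, path, factor_class)
    raise ValueError(f"unknown PWM dialect {dialect!r}")


_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*\[?\s*([-\d.eE+\s]*?)\s*\]?\s*$")


def _read_pwm_jaspar(text: str, path, factor_class) -> PWM:
    pwm_id = None
    rows: dict[str, list[float]] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if line.startswith(">"):
            pwm_id = line[1:].split()[0] if line[1:].split() else None
            continue
        m = _JASPAR_ROW.match(line)
        if not m:
            raise FormatError(f"unparseable JASPAR row: {line!r}", path, lineno)
        base, values = m.group(1), m.group(2).split()
        try:
            rows[base] = [float(v) for v in values]
        except ValueError:
            raise FormatError(f"non-numeric matrix entry in {line!r}",
                              path, lineno) from None
    if len(rows) != 4:
        raise FormatError(f"expected 4 base rows, got {len(rows)}", path, None)
    matrix = _normalize_matrix(rows, path)
    return PWM(id=pwm_id or Path(path).stem, matrix=matrix, factor_class=factor_class)


def _read_pwm_meme(text: str, path, factor_class) -> PWM:
    lines = text.splitlines()
    pwm_id = None
    cols: list[list[float]] = []
    in_matrix = False
    for lineno, line in enumerate(lines, start=1):
        stripped = line.strip()
        if stripped.startswith("MOTIF"):
            parts = stripped.split()
            if len(parts) < 2:
                raise FormatError("MOTIF line without identifier", path, lineno)
            pwm_id = parts[1]
        elif stripped.startswith("letter-probability matrix"):
            in_matrix = True
        elif in_matrix:
            if not stripped or not stripped[0].isdigit() and stripped[0] != ".":
                in_matrix = False
                continue
            vals = [float(v) for v in stripped.split()]
            if len(vals) != 4:
                raise FormatError(f"expected 4 probabilities per row, got {len(vals)}",
                                  path, lineno)
            cols.append(vals)
    if pwm_id is None or not cols:
        raise FormatError("no MOTIF block with a letter-probability matrix found",
                          path, None)
    rows = {b: [c[i] for c in cols] for i, b in enumerate(BASE_ORDER)}
    matrix = _normalize_matrix(rows, path)
    return PWM(id=pwm_id, matrix=matrix, factor_class=factor_class)


def _read_pwm_tsv(text: str, path, factor_class) -> PWM:
    pwm_id = None
    data_rows: list[list[float]] = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith(("#", ">")):
            tok = stripped.lstrip("#> ").split()
            pwm_id = tok[0] if tok else pwm_id
            continue
        tokens = stripped.replace("\t", " ").split()
        if tokens[0].upper() in BASE_INDEX and len(tokens) > 1:
            tokens = tokens[1:]
        try:
            data_rows.append([float(v) for v in tokens])
        except ValueError:
            raise FormatError(f"non-numeric matrix entry in {stripped!r}",
                              path, lineno) from None
    if len(data_rows) != 4:
        raise FormatError(f"expected 4 numeric rows, got {len(data_rows)}", path, None)
    rows = {b: data_rows[i] for i, b in enumerate(BASE_ORDER)}
    matrix = _normalize_matrix(rows, path)
    return PWM(id=pwm_id or Path(path).stem, matrix=matrix, factor_class=factor_class)


def write_pwm_jaspar(pwm: PWM, path, decimals: int = 6) -> None:
    """Serialize a PWM as JASPAR single-matrix text (probability rows)."""
    with open(path, "w") as fh:
        header = f">{pwm.id}"
        if pwm.factor_class:
            header += f" {pwm.factor_class}"
        fh.write(header + "\n")
        for i, base in enumerate(BASE_ORDER):
            vals = " ".join(f"{v:.{decimals}f}" for v in pwm.matrix[i])
            fh.write(f"{base} [ {vals} ]\n")
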