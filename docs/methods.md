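# Methods

## Model and procedure

A candidate cis-regulatory module is defined operationally as an anchor
ChIP-seq peak that carries every configured line of evidence:

- **Peak overlap.** For each required peak set *B* (Sp1 ChIP, FAIRE
  accessibility by default), the anchor interval must overlap some *B*
  interval by at least `min_b_fraction × length(B)` base pairs (and by at
  least 1 bp). The fraction is anchored on the *B* feature, which makes two
  readings expressible with one knob: `1.0` requires the whole *B* feature
  inside the anchor (full containment), and a tiny positive value
  (`ANY_OVERLAP = 1e-9`) degenerates to "any overlap ≥ 1 bp", the
  conventional default for peak-vs-peak comparison.
- **Motif containment.** For each required factor class, at least one PWM
  hit of that class must satisfy the same overlap test against the anchor;
  the default fraction here is `1.0` — the entire hit inside the peak.
  Multiple matrices configured for one class are OR-combined.
- **Annotation.** Survivors are assigned the nearest transcript; distance
  is unsigned, 0 on any overlap, otherwise the gap between closest edges in
  bp. Ties break toward the smaller transcript start, then the
  lexicographically smaller transcript id. The transcript's strand is
  recorded so users can derive orientation; upstream/downstream is not
  distinguished.

The anchor's coordinates are reported verbatim through every step, so the
output is always a subset of the anchor peak file. Filtering steps commute
(each is a per-anchor predicate), which the test suite verifies as
order-invariance; the sequential formulation is kept because it mirrors how
such screens are run and logged in practice — each step logs input count,
output count and the requirement applied.

Two stock configurations: the **full logic** requires the Sp1 peak overlap
and all four motif classes; the **relaxed logic** removes both Sp1
requirements (peak and motif). Removing requirements can only grow the
candidate set, so full ⊆ relaxed holds by construction and is asserted on
every synthetic dataset in the suite.

## PWM scanning

Matrices are stored as 4 × W column-normalized probabilities (counts are
normalized on read; probability columns must sum to 1 ± 1e-6). A window is
scored as the sum of its per-position base weights; the minus strand is
scored by applying the reverse-complemented matrix to the forward sequence,
so hit coordinates always refer to the forward strand.

- **Threshold convention.** "80 %" is interpreted as
  `0.80 × max_score`, where `max_score` is the sum of column maxima — the
  percent-of-highest-possible-score semantics that a percentage cutoff
  carries when probability matrices are scanned (verified in the test suite
  against Biostrings `matchPWM` with `min.score = "80%"`). An alternative
  `min_score + f·(max_score − min_score)` convention is available behind
  `threshold_convention="minmax"` for sensitivity analysis; the two agree
  at `f = 1`.
- **Strands.** Both strands are scanned by default; a forward-only mode
  exists because single-strand scans are a plausible alternative reading,
  and candidate counts under each mode should be compared rather than
  assumed.
- **N handling.** Windows containing `N` are disqualified outright rather
  than scored with a partial sum, avoiding threshold-dependent artifacts at
  assembly gaps. Readers fold any non-ACGT character to `N` with a warning.
- **Scoring is as-is.** Probability matrices are scored without log-odds or
  pseudocounts by default; `log_odds()` (uniform background, pseudocount
  0.01, shifted non-negative) is provided for reuse beyond this screen.
- All overlapping and abutting hits are reported; no greedy non-overlap
  selection. The downstream peak-level unique step makes hit multiplicity
  immaterial to candidate membership (it is reported as evidence counts).

The scanner is vectorized (per-column gather-and-sum over an integer-coded
sequence) but its contract is the exhaustive window enumeration, against
which it is tested on randomized genomes, including N-containing ones.

## Interval engine

`intersect_report_a` reproduces report-A/unique semantics: each qualifying
A record is returned once, in input order, with unchanged coordinates. A B
feature exactly coextensive with an A interval counts as fully contained
(overlap = length(B) satisfies ≥ 1.0 × length(B)). Strand is ignored in all
intersections: peaks are unstranded and a motif hit on either strand may
satisfy containment. The implementation uses an interval tree per
chromosome, but the contract — and the acceptance check — is the all-pairs
oracle's answer.

Chromosome naming is literal (no "chr" aliasing); intervals naming a
chromosome absent from the genome are a hard error listing the orphans,
because silently empty intersections are the classic failure mode of this
kind of pipeline.

## Coordinates and formats

Everything internal is 0-based half-open (BED-native). GTF input (1-based
inclusive, `transcript` feature rows only) is converted on read. narrowPeak
summit `-1` maps to "absent" per the ENCODE convention. PWM dialects:
JASPAR single-matrix text, a minimal MEME motif block, and a bare 4-row
TSV. Which matrix serves which factor class is always named explicitly in
the configuration — the pipeline never guesses a database entry.

## Synthetic benchmark

The generator emulates the *structure* of a leg-disc-style input bundle:
a multi-chromosome i.i.d. background genome at configurable GC content
(default 0.42, fly-like), three partially overlapping peak sets, one PWM
per class (random consensus; probability `sharpness` on the consensus base,
default 0.9, remainder spread uniformly), and a transcript map.

- **True CRMs** (default 12, peak width 200–400 bp) are written identically
  into all three peak files (an optional outward jitter of the Sp1/FAIRE
  copies tests anchor semantics separately from overlap semantics) and
  carry one exact-consensus instance of every class, spaced at least one
  matrix-width apart so no window can span two instances.
- **Decoys** realize named single-condition failures: absent from one peak
  file, one motif class missing, absent from the anchor file, or a Dll
  instance straddling the anchor's left edge by exactly 1 bp (present but
  not fully contained — the containment boundary probe).
- **Scrubbing.** A decoy's "missing" class must not be satisfiable by
  background chance, so windows of that class scoring at or above the scrub
  threshold (default 0.8 of the matrix maximum, matching the default scan
  fraction) are mutated away, never touching planted-instance positions.
  Consensus sets are redrawn up front whenever any alignment of one class's
  matrix against another class's planted instance (either orientation, any
  offset) could stay above threshold on protected positions alone — that
  screening is what guarantees scrubbing terminates. Scrub positions and
  replacement bases are drawn from the seeded generator, since overlapping
  offender windows share positions and a deterministic fix-up rule can flip
  a shared base back and forth indefinitely. Running the pipeline at a scan
  fraction below the scrub fraction voids the decoy guarantee.
- **Determinism.** One `numpy` Generator seeded from `SimulationConfig.seed`
  drives every draw; two runs with one seed produce byte-identical corpora,
  and the truth ledger is serialized as documented TSVs so evaluation can be
  re-run without regeneration.
- **Sampled-instance mode.** `sample_instances=True` draws planted instance
  bases from the PWM columns instead of writing the exact consensus; only
  then can planted instances fall below threshold, which is what the graded
  recall-degradation test exercises. The default stays exact-consensus so
  that true CRMs satisfy all conditions by construction.

What passing the benchmark does **not** show: the generator has no ChIP-seq
read noise, fragment pileups, peak-caller boundary error, Markovian or
repeat-structured background, or realistic motif co-occurrence. Perfect
recovery on synthetic data validates the *logic and bookkeeping* of the
screen (containment semantics, anchor fidelity, criteria monotonicity,
determinism), not its sensitivity or specificity on real chromatin.

`evaluate_recovery` matches predictions to truth by interval identity
against the anchor coordinates; precision is defined as 1.0 when there are
no predictions, recall as 1.0 when there is no truth.

## Problem sizes and numerical choices

The shipped test and acceptance runs use 3 × 30–50 kb chromosomes, 5–12
true CRMs, 1–3 decoys per pattern, and 20 seeds per multi-seed property —
sizes at which every stage can also be checked against its brute-force
oracle. Score comparisons between the vectorized scanner and the
plain-Python oracle are made at 6 decimal places (summation order differs
at ~1e-15 relative error); emitted hits use `score ≥ threshold` with exact
float comparison, and the threshold itself is `fraction × max_score`
computed once per scan. Empty inputs are contract-level cases: a matrix
wider than every chromosome yields an empty hit list with a warning; an
empty transcript set is an error, while a query chromosome with no
transcript yields an unannotated record with a warning.

## Open design points resolved here

- The anchor ("the initial file" whose coordinates are reported) is the
  Dll ChIP peak set by default and configurable; Dll is the factor common
  to both logics, and a single anchor is required for output coordinates to
  be well-defined.
- The criteria enumerate to seven logical conditions (anchor membership,
  two peak overlaps, four motif classes); all are independent toggles. One
  of them — being an anchor peak — is structural, so single-removal
  monotonicity is quantified over the six removable requirements.
- "Excluding Sp1 as a factor" is read as removing *both* the Sp1 peak and
  the Sp1 motif requirement; the configuration can express either variant.
- Peak-vs-peak steps default to ≥ 1 bp overlap, motif steps to full
  containment; both are per-step configuration, because requiring one whole
  peak inside another would be an implausibly strict reading for
  peak–peak comparison.

## Known limitations

- No p-value calibration of motif scores, higher-order background models,
  or motif discovery; thresholds are percent-of-maximum only.
- No BAM/FASTQ handling or peak calling — peaks are consumed as called.
- Nearest-transcript assignment is distance-only; no promoter/TSS logic.
- The benchmark's guarantees are conditional on scanning at or above the
  scrub fraction and on exact-consensus planting.
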