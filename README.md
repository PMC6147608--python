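# crmscan

Combinatorial prediction of cis-regulatory modules (CRMs) from
transcription-factor occupancy, chromatin accessibility and motif content.

## The problem

Enhancers that drive patterned gene expression in developing tissues — for
example the Drosophila leg imaginal disc — typically integrate several
transcription-factor inputs at once. A productive way to find them
genome-wide is to demand *combinatorial* evidence: a region should be bound
in vivo by the relevant factors (ChIP-seq peaks), lie in open chromatin
(FAIRE-seq peaks), and contain recognizable binding sites (position-weight-
matrix hits) for every factor of the regulatory logic under study.

`crmscan` implements that screen as a reusable, tested pipeline:

1. **PWM genome scan.** Each factor class (Dll, Sp1, Pan/TCF, Mad by
   default) has one or more PWMs; every window of every chromosome is
   scored on both strands as the sum of per-position base weights
   `S(w) = Σ_j M[b_j, j]`, and windows with `S ≥ f · S_max` are kept
   (default `f = 0.80`, i.e. 80 % of the highest attainable score).
2. **Sequential intersection.** An *anchor* peak set (Dll ChIP by default)
   is filtered by overlap with the other required peak sets, then by full
   containment (`-F 1.0`-style: the whole motif hit inside the peak) of at
   least one hit per required motif class — always reporting the anchor
   peak's own coordinates.
3. **Annotation.** Each surviving candidate is assigned its nearest
   annotated transcript with an unsigned edge-to-edge distance.

Two criteria sets are built in: the **full logic** (Dll + Sp1 peaks,
accessibility, and Dll/Sp1/Pan/Mad motifs) and the **relaxed logic** with
all Sp1 requirements removed, which by construction yields a superset of
candidates.

Because real peak calls are input-version-dependent, the package ships a
seeded **synthetic benchmark**: it plants true CRMs (satisfying every
condition) and decoys (each failing exactly one named condition, including
a motif straddling the peak edge by 1 bp) into a random genome, and scores
pipeline recovery against that ground truth.

## Worked example

Generate a synthetic corpus, run the full logic, and score recovery:

```bash
crmscan simulate --seed 3 --outdir corpus
# 12 true CRMs, 16 decoys -> corpus

cat > run.yaml <<'YAML'
inputs:
  genome: corpus/genome.fa
  peaks:
    dll_chip: corpus/dll_chip.bed
    sp1_chip: corpus/sp1_chip.bed
    faire: corpus/faire.bed
  transcripts: corpus/transcripts.bed
  pwms:
    dll: corpus/pwm_dll.jaspar
    sp1: corpus/pwm_sp1.jaspar
    pan: corpus/pwm_pan.jaspar
    mad: corpus/pwm_mad.jaspar
criteria:
  logic: full
output:
  prefix: out/candidates
YAML
crmscan pipeline --config run.yaml
# 12 candidates -> out/candidates.tsv

crmscan evaluate --predicted out/candidates.bed --truth corpus/truth.tsv
# {
#   "false_negatives": 0,
#   "false_positives": 0,
#   "precision": 1.0,
#   "recall": 1.0,
#   "true_positives": 12
# }
```

All 12 planted CRMs are recovered and all 16 decoys rejected: each decoy
fails exactly one condition (a missing Sp1 peak, an absent Mad motif, an
edge-straddling Dll site, ...), so the full logic excludes it, while
relaxing precisely that condition re-admits it. The candidate table carries
the anchor-peak coordinates, nearest gene/transcript and distance, and
per-class contained-hit counts:

```
chrom  start  end    gene_id    transcript_id  distance  n_dll_hits  n_mad_hits ...
chr1   10162  10541  gene_0002  tx_0002        0         1           7
```

The same machinery is exposed piecewise: `crmscan scan` (PWM hits to BED),
`crmscan intersect` (report-A/unique intersection with a B-anchored overlap
fraction), `crmscan annotate` (nearest-transcript table) — or as library
functions (`scan_sequence`, `intersect_report_a`, `nearest_transcript`,
`run_full_logic`, `run_relaxed_logic`, `simulate`, `evaluate_recovery`).

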