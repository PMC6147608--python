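"""Synthetic benchmark generator: determinism, planted ground truth,
decoy semantics and recovery scoring."""

import filecmp

import pytest

from crmscan import (ANY_OVERLAP, CriteriaConfig, GenomicInterval,
                     SimulationConfig, evaluate_recovery, read_truth,
                     run_full_logic, run_pipeline, scan_sequence, simulate)
from crmscan.synthetic_data import (DEFAULT_DECOY_PATTERNS,
                                    MOTIF_CLASSES, PwmSpec)

SMALL = dict(n_true_crms=5, n_decoys_per_pattern=1, n_transcripts=10)


def sharp(cfg_kwargs=None, **kw):
    specs = {"dll": PwmSpec(8, 1.0), "sp1": PwmSpec(10, 1.0),
             "pan": PwmSpec(9, 1.0), "mad": PwmSpec(6, 1.0)}
    return SimulationConfig(pwm_specs=specs, **{**SMALL, **(cfg_kwargs or {}),
                                                **kw})


def test_same_seed_gives_byte_identical_corpora(tmp_path):
    for d in ("a", "b"):
        simulate(SimulationConfig(seed=7, **SMALL), outdir=tmp_path / d)
    files = sorted(p.name for p in (tmp_path / "a").iterdir())
    assert files
    match, mismatch, errors = filecmp.cmpfiles(
        tmp_path / "a", tmp_path / "b", files, shallow=False)
    assert mismatch == [] and errors == []


def test_different_seeds_differ(tmp_path):
    d1 = simulate(SimulationConfig(seed=1, **SMALL))
    d2 = simulate(SimulationConfig(seed=2, **SMALL))
    assert d1.genome != d2.genome


def test_every_true_crm_contains_each_planted_class(rng):
    """At sharpness 1.0, scanning the emitted sequence at fraction 1.0 finds
    at least one hit of every class inside every true CRM."""
    data = simulate(sharp(seed=3, n_true_crms=10))
    for cls in MOTIF_CLASSES:
        hits = scan_sequence(data.genome, data.pwms[cls][0],
                             min_score_fraction=1.0)
        for crm in data.truth.true_crms:
            assert any(h.interval.chrom == crm.chrom
                       and h.interval.start >= crm.start
                       and h.interval.end <= crm.end for h in hits), \
                f"true CRM {crm.name} lacks a contained {cls} hit"


def test_planted_hits_ledger_matches_sequence(rng):
    data = simulate(SimulationConfig(seed=5, **SMALL))
    for h in data.truth.planted_hits:
        seq = data.genome[h.interval.chrom][h.interval.start:h.interval.end]
        pwm = data.pwms[h.factor_class][0]
        from crmscan import window_score
        assert window_score(pwm, seq, h.strand) == pytest.approx(pwm.max_score)


def test_decoys_and_true_crms_are_disjoint():
    data = simulate(SimulationConfig(seed=9, **SMALL))
    regions = list(data.truth.true_crms) + [
        iv for lst in data.truth.decoys.values() for iv in lst]
    for i, x in enumerate(regions):
        for y in regions[i + 1:]:
            assert x.chrom != y.chrom or x.end <= y.start or y.end <= x.start


def test_straddling_decoy_probes_containment_boundary():
    """The edge-straddling motif is rejected under full containment and
    admitted in >=1 bp overlap mode."""
    data = simulate(sharp(seed=13))
    straddles = {(iv.chrom, iv.start, iv.end)
                 for iv in data.truth.decoys["straddle_dll"]}
    strict = run_full_logic(data.genome, data.peaks, data.pwms,
                            data.transcripts)
    assert not straddles & {(c.interval.chrom, c.interval.start,
                             c.interval.end) for c in strict}
    loose_cfg = CriteriaConfig(motif_requirements={
        cls: {"min_score_fraction": 0.80,
              "min_b_fraction": ANY_OVERLAP if cls == "dll" else 1.0}
        for cls in MOTIF_CLASSES})
    loose = run_pipeline(data.genome, data.peaks, data.pwms,
                         data.transcripts, loose_cfg)
    assert straddles <= {(c.interval.chrom, c.interval.start, c.interval.end)
                         for c in loose}


def test_each_decoy_pattern_is_readmitted_only_by_its_own_relaxation():
    data = simulate(sharp(seed=17))
    config = CriteriaConfig()
    full = {(c.interval.chrom, c.interval.start, c.interval.end)
            for c in run_full_logic(data.genome, data.peaks, data.pwms,
                                    data.transcripts)}
    removable = set(config.requirement_names)
    for pat in DEFAULT_DECOY_PATTERNS:
        keys = {(iv.chrom, iv.start, iv.end)
                for iv in data.truth.decoys[pat.name]}
        assert not keys & full, f"{pat.name} leaked into the full logic"
        if pat.failed_condition not in removable or pat.straddle:
            continue
        readmitting = {(c.interval.chrom, c.interval.start, c.interval.end)
                       for c in run_pipeline(
                           data.genome, data.peaks, data.pwms,
                           data.transcripts,
                           config.without(pat.failed_condition))}
        assert keys <= readmitting, \
            f"removing {pat.failed_condition} did not re-admit {pat.name}"
        for other in removable - {pat.failed_condition}:
            others = {(c.interval.chrom, c.interval.start, c.interval.end)
                      for c in run_pipeline(
                          data.genome, data.peaks, data.pwms,
                          data.transcripts, config.without(other))}
            assert not keys & others, \
                f"{pat.name} re-admitted by unrelated removal of {other}"


def test_recall_degrades_monotonically_with_sharpness(rng):
    """With instances sampled from the PWM (rather than exact consensus),
    lowering sharpness pushes more planted instances below the scan
    threshold; recall must never increase as sharpness drops."""
    recalls = []
    for s in (1.0, 0.7, 0.45):
        specs = {c: PwmSpec(w, s) for c, w in
                 (("dll", 8), ("sp1", 10), ("pan", 9), ("mad", 6))}
        data = simulate(SimulationConfig(seed=23, pwm_specs=specs,
                                         scrub_fraction=0.95,
                                         sample_instances=True, **SMALL))
        cfg = CriteriaConfig(motif_requirements={
            c: {"min_score_fraction": 0.95, "min_b_fraction": 1.0}
            for c in MOTIF_CLASSES})
        found = run_pipeline(data.genome, data.peaks, data.pwms,
                             data.transcripts, cfg)
        recalls.append(evaluate_recovery(found, data.truth)["recall"])
    assert recalls == sorted(recalls, reverse=True)


def test_jitter_keeps_peak_overlap():
    data = simulate(sharp(seed=29, cfg_kwargs={"peak_jitter_bp": 25}))
    found = run_full_logic(data.genome, data.peaks, data.pwms,
                           data.transcripts)
    r = evaluate_recovery(found, data.truth)
    assert r["recall"] == 1.0 and r["precision"] == 1.0


def test_impossible_layout_errors():
    with pytest.raises(ValueError, match="larger"):
        simulate(SimulationConfig(seed=1, n_chroms=1, chrom_length=2000,
                                  n_true_crms=50))


def test_truth_ledger_round_trip(tmp_path):
    data = simulate(SimulationConfig(seed=31, **SMALL), outdir=tmp_path)
    truth = read_truth(tmp_path / "truth.tsv")
    assert truth.true_crms == [
        GenomicInterval(iv.chrom, iv.start, iv.end, name=iv.name)
        for iv in data.truth.true_crms]
    assert {k: [(i.chrom, i.start, i.end) for i in v]
            for k, v in truth.decoys.items()} == \
        {k: [(i.chrom, i.start, i.end) for i in v]
         for k, v in data.truth.decoys.items()}
    assert truth.patterns["no_faire"].mask == data.truth.patterns["no_faire"].mask


# --- evaluate_recovery ------------------------------------------------------

def _iv(s):
    return GenomicInterval("chr1", s, s + 10)


def test_perfect_prediction_scores_one():
    truth = simulate(SimulationConfig(seed=2, **SMALL)).truth
    r = evaluate_recovery(list(truth.true_crms), truth)
    assert r["precision"] == 1.0 and r["recall"] == 1.0
    assert r["false_positives"] == r["false_negatives"] == 0


def test_empty_predictions_convention():
    truth = simulate(SimulationConfig(seed=2, **SMALL)).truth
    r = evaluate_recovery([], truth)
    assert r["precision"] == 1.0 and r["recall"] == 0.0


def test_confusion_counts_match_set_arithmetic(rng):
    truth = simulate(SimulationConfig(seed=2, **SMALL)).truth
    true_set = list(truth.true_crms)
    predicted = true_set[:3] + [_iv(100_000), _iv(200_000)]
    r = evaluate_recovery(predicted, truth)
    assert (r["true_positives"], r["false_positives"],
            r["false_negatives"]) == (3, 2, len(true_set) - 3)
    assert r["precision"] == pytest.approx(3 / 5)
    assert r["recall"] == pytest.approx(3 / len(true_set))
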