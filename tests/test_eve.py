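"""Endogenous viral element screening: genome scan, DNA coverage, verdicts."""

import numpy as np
import pytest

from aranevir._seq import revcomp
from aranevir.eve import (
    EveThresholds,
    GenomeHit,
    IntegrationEvidence,
    classify_exogenous,
    dna_read_coverage,
    scan_integration,
)
from aranevir.synth import plant_eve


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestScanIntegration:
    def test_exact_copy_found_full_length(self):
        rng = np.random.default_rng(1)
        cand = _random_seq(rng, 500)
        genome = _random_seq(rng, 2000) + cand + _random_seq(rng, 1000)
        (hit, *_) = scan_integration(cand, genome)
        assert hit.length == 500
        assert hit.pct_identity == 100.0
        assert hit.genome_start == 2001

    def test_diverged_copy_recovered(self):
        rng = np.random.default_rng(2)
        cand = _random_seq(rng, 1000)
        genome, rec = plant_eve(_random_seq(rng, 5000), cand, divergence=0.1, seed=9)
        hits = scan_integration(cand, genome, min_id=85.0)
        assert hits, "diverged EVE copy missed"
        assert hits[0].length >= 100
        assert hits[0].pct_identity >= 85.0

    def test_reverse_strand_copy_found(self):
        rng = np.random.default_rng(3)
        cand = _random_seq(rng, 400)
        genome = _random_seq(rng, 1000) + revcomp(cand) + _random_seq(rng, 500)
        hits = scan_integration(cand, genome)
        assert hits and hits[0].strand == "-"

    def test_absent_candidate_no_hits(self):
        rng = np.random.default_rng(4)
        assert scan_integration(_random_seq(rng, 600), _random_seq(rng, 20000)) == []

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            scan_integration("ACGT" * 100, "ACGT" * 1000, k=10)

    def test_empty_genome_rejected(self):
        with pytest.raises(ValueError):
            scan_integration("ACGT" * 100, "")

    def test_agrees_with_sliding_window_oracle(self):
        """Seed-and-extend equals naive per-diagonal window search."""
        rng = np.random.default_rng(6)
        cand = _random_seq(rng, 300)
        copy = list(cand[40:260])
        for i in rng.choice(len(copy), size=12, replace=False):  # ~5% divergence
            copy[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[copy[i]]
        genome = _random_seq(rng, 700) + "".join(copy) + _random_seq(rng, 500)
        got = scan_integration(cand, genome, k=31, min_id=90.0, min_len=60)
        expected = _oracle_scan(cand, genome, k=31, min_id=90.0, min_len=60)
        got_spans = {(h.strand, h.cand_start, h.cand_end, h.genome_start, h.genome_end)
                     for h in got}
        assert got_spans == expected


def _oracle_scan(cand, genome, k, min_id, min_len):
    """Naive reference: per diagonal, leftmost-longest qualifying window."""
    out = set()
    f = 1.0 - min_id / 100.0
    for strand, gseq in (("+", genome), ("-", revcomp(genome))):
        for diag in range(-(len(cand) - 1), len(gseq)):
            c_lo = max(0, -diag)
            g_lo = c_lo + diag
            span = min(len(cand) - c_lo, len(gseq) - g_lo)
            if span < min_len:
                continue
            mism = [cand[c_lo + i] != gseq[g_lo + i] for i in range(span)]
            best = (0, 0)
            for s in range(span):
                if mism[s]:
                    continue
                bad = 0
                for e in range(s, span):
                    if mism[e]:
                        bad += 1
                    if not mism[e] and bad <= f * (e - s + 1):
                        if e - s + 1 > best[1] - best[0]:
                            best = (s, e + 1)
            s, e = best
            if e - s < min_len:
                continue
            run = best_run = 0
            for i in range(s, e):
                run = 0 if mism[i] else run + 1
                best_run = max(best_run, run)
            if best_run < k:
                continue
            gs, ge = g_lo + s, g_lo + e - 1
            if strand == "-":
                gs, ge = len(gseq) - 1 - ge, len(gseq) - 1 - gs
            out.add((strand, c_lo + s + 1, c_lo + e, gs + 1, ge + 1))
    return out


class TestDnaReadCoverage:
    def test_full_tiling_gives_one(self):
        rng = np.random.default_rng(7)
        cand = _random_seq(rng, 400)
        reads = {f"r{i}": cand[p:p + 100] for i, p in enumerate(range(0, 301, 50))}
        assert dna_read_coverage(cand, reads) == 1.0

    def test_half_tiling_half_covered(self):
        rng = np.random.default_rng(8)
        cand = _random_seq(rng, 400)
        reads = {"r0": cand[:200]}
        assert dna_read_coverage(cand, reads) == pytest.approx(0.5)

    def test_unrelated_reads_give_zero(self):
        rng = np.random.default_rng(9)
        cand = _random_seq(rng, 400)
        reads = {f"r{i}": _random_seq(rng, 100) for i in range(30)}
        assert dna_read_coverage(cand, reads) == 0.0

    def test_no_reads_warns(self):
        with pytest.warns(UserWarning):
            assert dna_read_coverage("ACGT" * 50, {}) == 0.0

    def test_reverse_strand_reads_count(self):
        rng = np.random.default_rng(10)
        cand = _random_seq(rng, 200)
        reads = {"r0": revcomp(cand)}
        assert dna_read_coverage(cand, reads) == 1.0


def _hit(length, ident):
    return GenomeHit("g", "+", 1, length, 1, length, length, ident)


class TestClassifyExogenous:
    def test_clean_candidate_is_bona_fide(self):
        ev = IntegrationEvidence("c", [], 0.0)
        assert classify_exogenous(ev) == "bona_fide"

    def test_strong_genome_hit_is_eve(self):
        assert classify_exogenous(IntegrationEvidence("c", [_hit(500, 98.0)], 0.0)) == "EVE"

    def test_dna_coverage_alone_is_eve(self):
        assert classify_exogenous(IntegrationEvidence("c", [], 0.25)) == "EVE"

    def test_near_threshold_hit_is_ambiguous(self):
        ev = IntegrationEvidence("c", [_hit(120, 87.0)], 0.0)
        assert classify_exogenous(ev, EveThresholds(min_id=90.0)) == "ambiguous"

    def test_short_hit_ignored(self):
        ev = IntegrationEvidence("c", [_hit(50, 99.0)], 0.0)
        assert classify_exogenous(ev) == "bona_fide"

    def test_dataset_verdicts(self, ds1):
        """Planted EVE flagged; exogenous viruses all bona fide."""
        thresholds = EveThresholds()
        verdicts = {}
        for seg in ds1.truth.segments:
            seq = ds1.transcripts[seg.transcript_id]
            hits = scan_integration(seq, ds1.host_genome,
                                    min_id=thresholds.min_id - thresholds.ambiguous_margin)
            cov = dna_read_coverage(seq, ds1.dna_reads)
            verdicts[seg.virus] = classify_exogenous(
                IntegrationEvidence(seg.segment_id, hits, cov), thresholds)
        assert verdicts.pop("eve_like") == "EVE"
        assert set(verdicts.values()) == {"bona_fide"}
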