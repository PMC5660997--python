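"""Generator determinism, planted-truth invariants and count simulation."""

import numpy as np
import pandas as pd
import pytest

from aranevir.annotate import pairwise_identity
from aranevir.quantify import fpkm
from aranevir.synth import (
    ConfigurationError,
    GeneratorConfig,
    LibraryDesign,
    SegmentTruth,
    TruthRecord,
    VirusModel,
    build_dataset,
    default_config,
    plant_eve,
    simulate_library_counts,
)

from conftest import dataset


class TestDeterminism:
    def test_identical_outputs_for_same_seed(self):
        a = build_dataset(default_config(), seed=42)
        b = build_dataset(default_config(), seed=42)
        assert a.transcripts == b.transcripts
        assert a.reference_proteins == b.reference_proteins
        assert a.host_genome == b.host_genome
        assert a.counts.equals(b.counts)
        assert a.truth.to_json() == b.truth.to_json()

    def test_seeds_differ(self, ds1):
        other = dataset(2)
        assert other.transcripts != ds1.transcripts


class TestPlantedStructure:
    def test_ten_segment_virus_planted(self, ds1):
        reo = [s for s in ds1.truth.segments if s.virus == "reo_like"]
        assert len(reo) == 10
        assert all(s.transcript_id in ds1.transcripts for s in reo)

    def test_reference_identity_near_target(self, ds1):
        """References are planted proteins mutated to ~40% aa identity,
        re-verified here by global alignment."""
        segs = {s.segment_id: s for s in ds1.truth.segments}
        for ref_id, info in ds1.truth.reference_proteins.items():
            seg = segs[info["source_segment"]]
            seq = ds1.transcripts[seg.transcript_id]
            from aranevir.annotate import find_orfs

            protein = find_orfs(seq, min_aa=100)[0].protein
            ident = pairwise_identity(protein, ds1.reference_proteins[ref_id], level="aa")
            assert ident == pytest.approx(40.0, abs=5.0)

    def test_host_transcripts_carry_no_planted_orfs(self, ds1):
        assert set(ds1.host_ids).isdisjoint(ds1.viral_ids)
        assert len(ds1.host_ids) == ds1.config.n_host_transcripts

    def test_invalid_model_rejected(self):
        bad = VirusModel(name="bad", architecture="multipartite",
                         segment_lengths=(500,), orf_layout=(((10, 100, "forward"),),))
        with pytest.raises(ConfigurationError, match="codons"):
            bad.validate()
        with pytest.raises(ConfigurationError):
            GeneratorConfig(viruses=()).validate()


class TestPlantEve:
    def test_zero_divergence_is_exact_copy(self):
        genome = "ACGT" * 300
        seg = "TTGACCA" * 30
        new, rec = plant_eve(genome, seg, divergence=0.0, seed=5)
        assert len(new) == len(genome) + len(seg)
        assert new[rec.start - 1:rec.end] == seg
        assert rec.realized_identity == 100.0

    def test_realized_identity_tracks_divergence(self):
        genome = "ACGT" * 500
        rng = np.random.default_rng(0)
        seg = "".join(rng.choice(list("ACGT"), 1000))
        new, rec = plant_eve(genome, seg, divergence=0.1, seed=5)
        inserted = new[rec.start - 1:rec.end]
        mismatches = sum(a != b for a, b in zip(inserted, seg))
        assert rec.realized_identity == pytest.approx(100.0 * (1 - mismatches / 1000))
        assert rec.realized_identity == pytest.approx(90.0, abs=3.0)

    def test_two_inserts_additive(self):
        genome = "ACGT" * 300
        seg = "TTGACCA" * 20
        g1, r1 = plant_eve(genome, seg, 0.0, seed=1)
        g2, r2 = plant_eve(g1, seg, 0.0, seed=2)
        assert len(g2) == len(genome) + 2 * len(seg)

    def test_segment_longer_than_genome_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            plant_eve("ACGT", "ACGTACGT", 0.1, seed=1)

    def test_divergence_bounds(self):
        with pytest.raises(ValueError):
            plant_eve("ACGT" * 100, "ACGTACGT", 0.5, seed=1)


def _one_segment_truth(length=2000):
    return TruthRecord(seed=0, segments=[
        SegmentTruth("segA", "vx", "segA", length, orfs=[]),
    ])


def _designs(n, infected=True, scale=50.0, reads=10_000_000):
    return [
        LibraryDesign(f"L{i:03d}", "I1", "brain", reads,
                      {"vx": infected}, {"vx": scale})
        for i in range(n)
    ]


class TestSimulateCounts:
    def test_uninfected_libraries_all_zero(self):
        counts = simulate_library_counts(_one_segment_truth(), _designs(20, infected=False), seed=3)
        assert (counts.to_numpy() == 0).all()

    def test_mean_matches_fpkm_parameterisation(self):
        """scale 50, 2 kb segment, 10 M host reads -> mean count 1000."""
        counts = simulate_library_counts(_one_segment_truth(), _designs(200), seed=3)
        assert counts.loc["segA"].mean() == pytest.approx(1000, rel=0.10)

    def test_expected_fpkm_equals_abundance_scale(self):
        counts = simulate_library_counts(_one_segment_truth(), _designs(200), seed=4)
        est = fpkm(counts.loc["segA"].to_numpy(), 2000, 10_000_000)
        assert est.mean() == pytest.approx(50.0, rel=0.10)

    def test_segments_share_infection_pattern(self, ds1):
        """All segments of one virus are nonzero in exactly the infected libraries."""
        by_virus = ds1.truth.viruses()
        for virus, segs in by_virus.items():
            infected = [d.library_id for d in ds1.designs if d.infection_status[virus]]
            uninfected = [d.library_id for d in ds1.designs if not d.infection_status[virus]]
            for seg in segs:
                row = ds1.counts.loc[seg.transcript_id]
                assert (row[uninfected] == 0).all()
                assert (row[infected] > 0).all()

    def test_missing_virus_in_design_rejected(self):
        designs = [LibraryDesign("L1", "I1", "brain", 1_000_000, {}, {})]
        with pytest.raises(ConfigurationError):
            simulate_library_counts(_one_segment_truth(), designs, seed=1)
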