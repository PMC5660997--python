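"""ORF coordinate arithmetic, masses, UTR composition and global identity."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from aranevir.annotate import (
    CoordinateError,
    find_orfs,
    orf_aa_length,
    pairwise_identity,
    protein_mass_kda,
    utr_profile,
)
from aranevir._seq import revcomp

NT = st.sampled_from("ACGT")


class TestOrfArithmetic:
    @pytest.mark.parametrize("start,end,aa", [
        (7948, 9747, 599),
        (56, 7285, 2409),
        (1, 6, 1),  # one codon plus its stop
    ])
    def test_stop_inclusive_convention(self, start, end, aa):
        assert orf_aa_length(start, end) == aa

    def test_span_not_codon_multiple_raises(self):
        with pytest.raises(CoordinateError, match="722-7226"):
            orf_aa_length(722, 7226)

    @given(start=st.integers(1, 10_000), n_codons=st.integers(2, 5_000))
    @settings(max_examples=50, derandomize=True)
    def test_aa_length_matches_span(self, start, n_codons):
        end = start + 3 * n_codons - 1
        assert orf_aa_length(start, end) == n_codons - 1


class TestProteinMass:
    def test_single_glycine(self):
        # residue 57.0519 Da + one water 18.015 Da
        assert protein_mass_kda("G") == pytest.approx(0.07507, abs=1e-4)

    def test_two_glycines(self):
        assert protein_mass_kda("GG") == pytest.approx(0.13212, abs=1e-4)

    def test_additivity_shares_one_water(self):
        a, b = "MKV", "WYERT"
        assert protein_mass_kda(a + b) == pytest.approx(
            protein_mass_kda(a) + protein_mass_kda(b) - 0.018015, abs=1e-9
        )

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="'J'"):
            protein_mass_kda("MKJ")


class TestFindOrfs:
    def test_minimal_forward_orf(self):
        orfs = find_orfs("AAATGAAATAA", min_aa=1)
        assert [(o.start, o.end, o.orientation, o.protein, o.aa_length) for o in orfs] == [
            (3, 11, "forward", "MK", 2)
        ]

    def test_no_atg_no_orfs(self):
        assert find_orfs("CCCCCCCCTAACCC", min_aa=1) == []

    def test_unterminated_orf_not_reported(self):
        assert find_orfs("CCATGAAAAAA", min_aa=1, both_strands=False) == []

    def test_reverse_orf_deposited_coordinates(self):
        fwd = "ATGAAATGGTAA"  # MKW + stop
        seq = "CC" + revcomp(fwd) + "GGG"
        (orf,) = [o for o in find_orfs(seq, min_aa=1) if o.orientation == "reverse"]
        assert (orf.start, orf.end) == (3, 14)
        assert orf.protein == "MKW"
        assert orf.start < orf.end  # orientation carries direction, never coords

    def test_reports_maximal_orf_per_stop(self):
        # two in-frame ATGs, one stop: the upstream ATG defines the ORF
        seq = "ATGAAAATGAAATAA"
        orfs = find_orfs(seq, min_aa=1, both_strands=False)
        assert [(o.start, o.end) for o in orfs] == [(1, 15)]

    def test_planted_truth_recovered_exactly(self, ds1):
        """Every planted segment's annotation equals the generator's truth."""
        for seg in ds1.truth.segments:
            seq = ds1.transcripts[seg.transcript_id]
            found = [
                {"start": o.start, "end": o.end, "orientation": o.orientation,
                 "aa_length": o.aa_length}
                for o in find_orfs(seq, min_aa=100)
            ]
            assert found == seg.orfs

    @given(seq=st.text(NT, min_size=30, max_size=120), min_aa=st.integers(1, 5))
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_orf_invariants(self, seq, min_aa):
        for o in find_orfs(seq, min_aa=min_aa):
            assert (o.end - o.start + 1) % 3 == 0
            assert o.aa_length == (o.end - o.start + 1) // 3 - 1
            assert o.start < o.end
            assert "*" not in o.protein


class TestUtrProfile:
    def test_uuua_counting(self):
        seq = "TTTATTTA" + "ATGAAATAA"
        orfs = find_orfs(seq, min_aa=1, both_strands=False)
        prof = utr_profile(seq, orfs, window=4, step=4)
        assert prof.utr5_len == 8
        assert prof.uuua_count == 2

    def test_orf_at_position_one(self):
        seq = "ATGAAATAA"
        prof = utr_profile(seq, find_orfs(seq, min_aa=1, both_strands=False), window=3, step=3)
        assert prof.utr5_len == 0 and prof.uuua_count == 0

    def test_planted_au_rich_utr5(self, ds1):
        """The picorna-like model's 760 nt 5'UTR is AU-rich as configured."""
        seg = next(s for s in ds1.truth.segments if s.virus == "picorna_like")
        seq = ds1.transcripts[seg.transcript_id]
        orfs = find_orfs(seq, min_aa=100)
        prof = utr_profile(seq, orfs, window=100, step=10)
        assert prof.utr5_len == 760
        utr_windows = [au for pos, gc, au in prof.windows if pos + 99 <= prof.utr5_len]
        assert sum(utr_windows) / len(utr_windows) >= 0.65
        for pos, gc, au in prof.windows:
            assert gc + au == pytest.approx(1.0)


class TestPairwiseIdentity:
    def test_identical_sequences(self):
        assert pairwise_identity("ACGTACGT", "ACGTACGT") == 100.0
        assert pairwise_identity("MKWVR", "MKWVR", level="aa") == 100.0

    def test_three_quarters(self):
        assert pairwise_identity("ACGT", "ACGA") == pytest.approx(75.0)

    @given(a=st.text(NT, min_size=1, max_size=12), b=st.text(NT, min_size=1, max_size=12))
    @settings(max_examples=40, derandomize=True, deadline=None)
    def test_symmetry(self, a, b):
        assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    @pytest.mark.parametrize("a,b", [
        ("ACGTAC", "AGTA"), ("AAAA", "TTTT"), ("ACG", "ACGTTT"), ("GATTAC", "GATAC"),
    ])
    def test_matches_exhaustive_alignment_enumeration(self, a, b):
        """Optimal global identity agrees with brute force over all alignments."""
        best_score, identities = _enumerate_global(a, b)
        assert pairwise_identity(a, b) in [pytest.approx(i) for i in identities]


def _enumerate_global(a, b, match=1.0, mismatch=-1.0, gap=-2.0):
    """All global alignments of a and b; returns (best score, identities at best).

    Identity is matches / alignment columns * 100, as the package defines it.
    """
    results = []

    def rec(i, j, score, matches, cols):
        if i == len(a) and j == len(b):
            results.append((score, 100.0 * matches / cols if cols else 100.0))
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            rec(i + 1, j + 1, score + (match if hit else mismatch), matches + hit, cols + 1)
        if i < len(a):
            rec(i + 1, j, score + gap, matches, cols + 1)
        if j < len(b):
            rec(i, j + 1, score + gap, matches, cols + 1)

    rec(0, 0, 0.0, 0, 0)
    best = max(s for s, _ in results)
    return best, {ident for s, ident in results if math.isclose(s, best)}
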