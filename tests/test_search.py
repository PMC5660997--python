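"""Six-frame translation, local alignment, E-values, and the discovery screen."""

import math
from functools import lru_cache

import pytest
from Bio.Align import substitution_matrices
from hypothesis import given, settings, strategies as st

from aranevir._seq import revcomp
from aranevir.annotate import translate_codons
from aranevir.search import (
    TranslatedHit,
    _frame_to_nt_span,
    collapse_hits,
    evalue,
    search,
    six_frame_translate,
    smith_waterman,
)

NT = st.sampled_from("ACGT")
B62 = substitution_matrices.load("BLOSUM62")


class TestSixFrameTranslate:
    def test_direct_codon_table(self):
        assert six_frame_translate("ATGAAATAG")[1] == "MK*"

    def test_n_codon_is_x(self):
        assert six_frame_translate("ATGNAA")[1] == "MX"

    def test_trailing_bases_dropped(self):
        frames = six_frame_translate("ATGAAAT")
        assert frames[1] == "MK" and frames[2] == "*N" and frames[3] == "E"

    def test_u_equals_t(self):
        assert six_frame_translate("AUGAAAUAG")[1] == "MK*"

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            six_frame_translate("")

    @given(seq=st.text(NT, min_size=3, max_size=60))
    @settings(max_examples=60, derandomize=True)
    def test_revcomp_symmetry(self, seq):
        """Frame +1 of the reverse complement equals frame -1 of the original."""
        assert six_frame_translate(revcomp(seq))[1] == six_frame_translate(seq)[-1]


def _brute_force_local(q, t, gap_open=11.0, gap_extend=1.0):
    """Best local alignment score by exhaustive path search (memoized).

    Enumerates every gapped extension from every start cell, charging
    gap_open for the first gapped column and gap_extend for each further
    one; any prefix may terminate.  Independent of the production aligner.
    """

    @lru_cache(maxsize=None)
    def best_from(i, j, state):
        options = [0.0]  # stop here
        if i < len(q) and j < len(t):
            options.append(B62[q[i], t[j]] + best_from(i + 1, j + 1, "M"))
        if i < len(q):
            options.append(-(gap_extend if state == "X" else gap_open) + best_from(i + 1, j, "X"))
        if j < len(t):
            options.append(-(gap_open if state != "Y" else gap_extend) + best_from(i, j + 1, "Y"))
        return max(options)

    return max(
        best_from(i, j, "M") for i in range(len(q) + 1) for j in range(len(t) + 1)
    )


class TestSmithWaterman:
    def test_self_alignment_scores_diagonal(self):
        s = "MKWVRTYHEA"
        aln = smith_waterman(s, s)
        assert aln.pct_identity == 100.0
        assert aln.score == sum(B62[c, c] for c in s)

    def test_textbook_pair_matches_enumeration(self):
        a = smith_waterman("HEAGAWGHEE", "PAWHEAE")
        assert a.score == _brute_force_local("HEAGAWGHEE", "PAWHEAE")

    def test_no_positive_pair_gives_empty_alignment(self):
        a = smith_waterman("WWWW", "GGGG")
        assert a.score == 0.0 and a.columns == 0

    def test_unknown_residue_named(self):
        with pytest.raises(ValueError, match="'U'"):
            smith_waterman("MKU", "MK")

    def test_stop_never_aligns(self):
        # '*' splits the alignable region: only one side of the stop aligns
        a = smith_waterman("MKWVR*HEAG", "MKWVRHEAG")
        assert a.score < smith_waterman("MKWVRHEAG", "MKWVRHEAG").score

    @given(
        q=st.text(NT, min_size=1, max_size=8),
        t=st.text(NT, min_size=1, max_size=8),
    )
    @settings(max_examples=60, derandomize=True, deadline=None)
    def test_matches_brute_force_enumeration(self, q, t):
        """DP local score equals exhaustive enumeration on short pairs."""
        assert smith_waterman(q, t).score == pytest.approx(_brute_force_local(q, t))


class TestEvalue:
    def test_formula_hand_arithmetic(self):
        # 0.041 * 100 * 1e5 * exp(-0.267 * 100)
        assert evalue(100, 100, 10**5) == pytest.approx(1.0402e-6, rel=1e-3)

    def test_monotone_and_limits(self):
        assert evalue(1000, 100, 1000) < 1e-100
        assert evalue(50, 100, 1000) > evalue(60, 100, 1000)

    def test_linear_in_database_size(self):
        assert evalue(80, 100, 2 * 10**5) == pytest.approx(2 * evalue(80, 100, 10**5))

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            evalue(10, 0, 100)
        with pytest.raises(ValueError):
            evalue(10, 10, 100, K=0.0)


class TestSearch:
    def test_planted_segments_recovered_no_host_hits(self, ds1, hits1):
        hit_transcripts = {h.transcript_id for h in hits1}
        assert ds1.viral_ids <= hit_transcripts
        assert not (hit_transcripts - ds1.viral_ids), "host transcript passed E-value filter"

    def test_all_hits_within_threshold(self, hits1):
        assert all(h.evalue <= 1e-5 for h in hits1)

    def test_best_frame_only_per_pair(self, hits1):
        seen = {(h.transcript_id, h.reference_id) for h in hits1}
        assert len(seen) == len(hits1)

    def test_zero_threshold_empty(self, ds1):
        few = dict(list(ds1.transcripts.items())[:3])
        assert search(few, ds1.reference_proteins, max_evalue=0.0) == []

    def test_empty_database_rejected(self, ds1):
        with pytest.raises(ValueError):
            search(ds1.transcripts, {})

    def test_frame_bookkeeping_roundtrip(self, ds1, hits1):
        """Re-translating the mapped nt span reproduces the aligned frame substring."""
        for h in hits1:
            seq = ds1.transcripts[h.transcript_id].upper().replace("U", "T")
            assert (h.t_end - h.t_start + 1) % 3 == 0
            if h.frame > 0:
                sub = seq[h.t_start - 1:h.t_end]
            else:
                rc = revcomp(seq)
                off = abs(h.frame) - 1
                lo = len(seq) - h.t_end + 1
                sub = rc[lo - 1:lo - 1 + (h.t_end - h.t_start + 1)]
            frames = six_frame_translate(seq)
            assert translate_codons(sub) in frames[h.frame]

    @given(
        seq=st.text(NT, min_size=12, max_size=60),
        frame=st.sampled_from([1, 2, 3, -1, -2, -3]),
        data=st.data(),
    )
    @settings(max_examples=60, derandomize=True)
    def test_nt_span_mapping_property(self, seq, frame, data):
        frames = six_frame_translate(seq)
        faa = frames[frame]
        if not faa:
            return
        qs = data.draw(st.integers(1, len(faa)))
        qe = data.draw(st.integers(qs, len(faa)))
        t_start, t_end = _frame_to_nt_span(frame, len(seq), qs, qe)
        assert 1 <= t_start < t_end <= len(seq)
        strand = seq if frame > 0 else revcomp(seq)
        lo = (abs(frame) - 1) + 3 * (qs - 1)
        assert translate_codons(strand[lo:lo + 3 * (qe - qs + 1)]) == faa[qs - 1:qe]


def _hit(tid, t_start, t_end, ref, ev, score=100.0):
    return TranslatedHit(tid, 1, t_start, t_end, ref, 1, (t_end - t_start + 1) // 3,
                         score, ev, 50.0)


class TestCollapseHits:
    def test_disjoint_hits_both_retained(self):
        hits = [_hit("t1", 1, 300, "refA", 1e-10), _hit("t1", 400, 700, "refB", 1e-8)]
        (cand,) = collapse_hits(hits)
        assert len(cand.hits) == 2

    def test_overlapping_hits_keep_lowest_evalue(self):
        hits = [
            _hit("t1", 1, 300, "refA", 1e-10),
            _hit("t1", 50, 350, "refB", 1e-8),
            _hit("t1", 100, 400, "refC", 1e-6),
        ]
        (cand,) = collapse_hits(hits)
        assert [h.reference_id for h in cand.hits] == ["refA"]

    def test_idempotent_on_duplicates(self):
        hits = [_hit("t1", 1, 300, "refA", 1e-10)]
        assert collapse_hits(hits + hits)[0].hits == collapse_hits(hits)[0].hits

    def test_one_candidate_per_transcript(self, hits1):
        cands = collapse_hits(hits1)
        assert len(cands) == len({h.transcript_id for h in hits1})
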