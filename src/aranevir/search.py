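"""Six-frame translated homology search of transcripts against viral proteins.

The discovery step mirrors a TBLASTN screen: every transcript is translated
in all six frames, each frame is aligned locally (Smith-Waterman, BLOSUM62,
gap open 11 / extend 1) against every reference viral protein, and hits are
kept when their Karlin-Altschul expectation falls below the configured
threshold (1e-5 by default).  The search is exhaustive rather than seeded:
no word heuristics, so scores are exact for the scoring scheme.  E-values
use ungapped Karlin-Altschul constants for BLOSUM62 (K = 0.041,
lambda = 0.267) as a monotone approximation; they are *not* bit-compatible
with NCBI BLAST, and the threshold is configurable to compensate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from ._seq import normalize_nt, revcomp
from .annotate import translate_codons

__all__ = [
    "TranslatedHit",
    "Candidate",
    "six_frame_translate",
    "smith_waterman",
    "LocalAlignment",
    "evalue",
    "search",
    "collapse_hits",
]

KARLIN_K = 0.041
KARLIN_LAMBDA = 0.267

# '*' (stop) must never align: local alignments are forced to stay within
# stop-free stretches of a reading frame.
_STOP_PENALTY = -1.0e6

_blosum62_nostop = None


def _matrix():
    global _blosum62_nostop
    if _blosum62_nostop is None:
        m = substitution_matrices.load("BLOSUM62")
        for sym in m.alphabet:
            m[sym, "*"] = _STOP_PENALTY
            m["*", sym] = _STOP_PENALTY
        _blosum62_nostop = m
    return _blosum62_nostop


def _local_aligner(gap_open: float, gap_extend: float) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _matrix()
    # Biopython charges open_gap_score for the first gapped column and
    # extend_gap_score for each further column: a length-k gap costs
    # gap_open + (k - 1) * gap_extend.
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


def six_frame_translate(nt_seq: str) -> dict[int, str]:
    """Translate a nucleotide sequence in frames +1..+3 and -1..-3.

    Frames -1..-3 are translations of the reverse complement; stop codons
    are rendered as ``*``, codons containing N as ``X``, and trailing
    partial codons are dropped.
    """
    s = normalize_nt(nt_seq)
    rc = revcomp(s)
    frames: dict[int, str] = {}
    for off in range(3):
        frames[off + 1] = translate_codons(s[off:])
        frames[-(off + 1)] = translate_codons(rc[off:])
    return frames


@dataclass(frozen=True)
class LocalAlignment:
    """Best local alignment between two protein sequences.

    Spans are 1-based inclusive; an empty alignment has score 0 and zeroed
    spans.
    """

    score: float
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    identities: int
    columns: int

    @property
    def pct_identity(self) -> float:
        return 100.0 * self.identities / self.columns if self.columns else 0.0


_EMPTY_ALIGNMENT = LocalAlignment(0.0, 0, 0, 0, 0, 0, 0)


def _check_residues(seq: str, alphabet: str) -> None:
    bad = set(seq) - set(alphabet)
    if bad:
        raise ValueError(f"unknown residue symbol(s): {sorted(bad)}")


def smith_waterman(
    query_aa: str,
    target_aa: str,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    *,
    score_only: bool = False,
) -> LocalAlignment:
    """Optimal local protein alignment under BLOSUM62 affine-gap scoring.

    A gap of length k costs ``gap_open + (k-1) * gap_extend``.  If no
    positive-scoring local alignment exists the empty alignment (score 0)
    is returned.  ``score_only`` skips the traceback (used by the search
    inner loop, where most pairs are then discarded).
    """
    if not query_aa or not target_aa:
        raise ValueError("smith_waterman requires non-empty sequences")
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    alphabet = _matrix().alphabet
    _check_residues(query_aa, alphabet)
    _check_residues(target_aa, alphabet)
    aligner = _local_aligner(gap_open, gap_extend)
    score = aligner.score(query_aa, target_aa)
    if score <= 0:
        return _EMPTY_ALIGNMENT
    if score_only:
        return LocalAlignment(score, 0, 0, 0, 0, 0, 0)
    aln = aligner.align(query_aa, target_aa)[0]
    qb, tb = aln.aligned[0], aln.aligned[1]
    identities = aln.counts().identities
    return LocalAlignment(
        score=score,
        q_start=int(qb[0][0]) + 1,
        q_end=int(qb[-1][1]),
        t_start=int(tb[0][0]) + 1,
        t_end=int(tb[-1][1]),
        identities=int(identities),
        columns=int(aln.length),
    )


def evalue(raw_score: float, m: int, n: int, K: float = KARLIN_K, lam: float = KARLIN_LAMBDA) -> float:
    """Karlin-Altschul expected number of chance hits: E = K * m * n * exp(-lambda * S)."""
    if K <= 0 or lam <= 0:
        raise ValueError("K and lambda must be positive")
    if m < 1 or n < 1:
        raise ValueError("sequence lengths must be >= 1")
    return K * m * n * math.exp(-lam * raw_score)


@dataclass(frozen=True)
class TranslatedHit:
    """A translated (TBLASTN-style) hit of a transcript frame on a reference protein."""

    transcript_id: str
    frame: int  # +1..+3 forward, -1..-3 reverse-complement frames
    t_start: int  # 1-based inclusive nt span on the transcript
    t_end: int
    reference_id: str
    r_start: int  # 1-based inclusive aa span on the reference protein
    r_end: int
    score: float
    evalue: float
    pct_identity: float

    def to_row(self) -> tuple:
        return (
            self.transcript_id, self.frame, self.t_start, self.t_end,
            self.reference_id, self.r_start, self.r_end,
            self.score, self.evalue, self.pct_identity,
        )


def _frame_to_nt_span(frame: int, seq_len: int, q_start: int, q_end: int) -> tuple[int, int]:
    """Map a 1-based aa span in a translation frame to deposited-strand nt coordinates."""
    off = abs(frame) - 1
    lo = off + 3 * (q_start - 1) + 1  # first nt of first codon, 1-based
    hi = off + 3 * q_end  # last nt of last codon
    if frame > 0:
        return lo, hi
    return seq_len - hi + 1, seq_len - lo + 1


def search(
    transcripts: dict[str, str],
    protein_db: dict[str, str],
    max_evalue: float = 1e-5,
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    min_frame_aa: int = 20,
) -> list[TranslatedHit]:
    """Screen transcripts against a viral protein reference set.

    For each (transcript, reference) pair only the best-scoring frame is
    reported, and only when its E-value is at or below ``max_evalue``.
    The database length for the E-value is the total number of reference
    residues (no edge-effect correction).
    """
    if not protein_db:
        raise ValueError("search requires a non-empty protein database")
    if not transcripts:
        return []
    db_len = sum(len(p) for p in protein_db.values())
    aligner = _local_aligner(gap_open, gap_extend)
    alphabet = _matrix().alphabet
    for rid, prot in protein_db.items():
        _check_residues(prot, alphabet)

    hits: list[TranslatedHit] = []
    for tid in sorted(transcripts):
        seq = normalize_nt(transcripts[tid])
        frames = six_frame_translate(seq)
        for rid in sorted(protein_db):
            prot = protein_db[rid]
            best_frame, best_score = 0, 0.0
            for frame, faa in frames.items():
                if len(faa) < min_frame_aa:
                    continue
                score = aligner.score(faa, prot)
                if score > best_score or (score == best_score and best_frame and frame > best_frame):
                    best_frame, best_score = frame, score
            if not best_frame:
                continue
            faa = frames[best_frame]
            e = evalue(best_score, len(faa), db_len)
            if e > max_evalue:
                continue
            aln = smith_waterman(faa, prot, gap_open, gap_extend)
            t_start, t_end = _frame_to_nt_span(best_frame, len(seq), aln.q_start, aln.q_end)
            hits.append(TranslatedHit(
                transcript_id=tid,
                frame=best_frame,
                t_start=t_start,
                t_end=t_end,
                reference_id=rid,
                r_start=aln.t_start,
                r_end=aln.t_end,
                score=aln.score,
                evalue=e,
                pct_identity=aln.pct_identity,
            ))
    hits.sort(key=lambda h: (h.transcript_id, h.evalue, -h.score, h.reference_id))
    return hits


@dataclass
class Candidate:
    """A non-redundant candidate: one transcript with its retained hits."""

    transcript_id: str
    hits: list[TranslatedHit] = field(default_factory=list)

    @property
    def best_hit(self) -> TranslatedHit:
        return self.hits[0]


def _overlap_fraction(a: TranslatedHit, b: TranslatedHit) -> float:
    lo = max(a.t_start, b.t_start)
    hi = min(a.t_end, b.t_end)
    if hi < lo:
        return 0.0
    shorter = min(a.t_end - a.t_start + 1, b.t_end - b.t_start + 1)
    return (hi - lo + 1) / shorter


def collapse_hits(hits: list[TranslatedHit], max_overlap: float = 0.5) -> list[Candidate]:
    """Collapse a hit list to one candidate per transcript.

    Within a transcript, hits whose nt spans overlap by more than
    ``max_overlap`` of the shorter span are redundant: the lowest E-value
    (ties: higher score, then lexicographic reference id) wins.  Disjoint
    hits are all retained on the same candidate.  Idempotent.
    """
    by_transcript: dict[str, list[TranslatedHit]] = {}
    for h in hits:
        by_transcript.setdefault(h.transcript_id, []).append(h)
    candidates = []
    for tid in sorted(by_transcript):
        ranked = sorted(set(by_transcript[tid]), key=lambda h: (h.evalue, -h.score, h.reference_id))
        kept: list[TranslatedHit] = []
        for h in ranked:
            if all(_overlap_fraction(h, k) <= max_overlap for k in kept):
                kept.append(h)
        candidates.append(Candidate(transcript_id=tid, hits=kept))
    return candidates
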