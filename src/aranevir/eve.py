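"""Endogenous viral element (EVE) screening.

A transcript that looks viral may be the expression product of a viral
sequence integrated in the host genome rather than an exogenous replicating
virus.  Two lines of evidence distinguish them:

* :func:`scan_integration` — exact k-mer seeds on the host genome assembly,
  extended along the diagonal (ungapped) into maximal segments whose
  identity stays at or above a threshold;
* :func:`dna_read_coverage` — the fraction of candidate positions covered
  by k-mers shared with host *DNA* reads (an unassembled integration leaves
  DNA-level traces even when the assembly missed it).

:func:`classify_exogenous` turns the evidence into a verdict: ``EVE`` when
either signal crosses its threshold, ``bona_fide`` when neither does, and
``ambiguous`` for genome hits just below the identity cutoff.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from ._seq import normalize_nt, revcomp

__all__ = [
    "GenomeHit",
    "IntegrationEvidence",
    "EveThresholds",
    "scan_integration",
    "dna_read_coverage",
    "classify_exogenous",
]


@dataclass(frozen=True)
class EveThresholds:
    """Decision thresholds; declared substitutes for a BLASTN E-value rule."""

    min_id: float = 90.0  # percent identity for a disqualifying genome hit
    min_len: int = 100  # nt; shorter matches are ignored
    cov_min: float = 0.1  # DNA-read k-mer coverage fraction
    ambiguous_margin: float = 5.0  # identity points below min_id still "ambiguous"


@dataclass(frozen=True)
class GenomeHit:
    genome_id: str
    strand: str  # '+' or '-'
    cand_start: int  # 1-based inclusive on the candidate
    cand_end: int
    genome_start: int  # 1-based inclusive on the genome (forward strand coords)
    genome_end: int
    length: int
    pct_identity: float


@dataclass
class IntegrationEvidence:
    candidate_id: str
    genome_hits: list[GenomeHit] = field(default_factory=list)
    dna_covered_fraction: float = 0.0
    verdict: str = ""


def _longest_window(mismatch: np.ndarray, max_mismatch_frac: float) -> tuple[int, int]:
    """Longest window [s, e) with mismatch fraction <= max_mismatch_frac.

    Windows are required to start and end on a match.  Returns (start, end)
    half-open, (0, 0) if none.  Leftmost longest wins.
    """
    n = len(mismatch)
    cum = np.concatenate(([0], np.cumsum(mismatch)))
    # g[i] = cum[i] - f*i ; window [s, e) feasible iff g[e] <= g[s]
    g = cum - max_mismatch_frac * np.arange(n + 1)
    best = (0, 0)
    # suffix maximum of index over positions sorted by g
    order = np.argsort(g, kind="stable")
    ranks = np.empty(n + 1, dtype=np.int64)
    ranks[order] = np.arange(n + 1)
    # suffix_max_idx[r] = max index among order[:r+1] -> need max e with g[e] <= g[s]:
    prefix_max_idx = np.maximum.accumulate(order)
    # for s, all e with g[e] <= g[s] are among order[:k] where k = number of
    # entries with g <= g[s]; with stable sort, find via searchsorted on sorted g
    g_sorted = g[order]
    for s in range(n):
        if mismatch[s]:
            continue
        k = np.searchsorted(g_sorted, g[s], side="right") - 1
        e = int(prefix_max_idx[k])
        # trim trailing mismatches so the window ends on a match
        while e > s and mismatch[e - 1]:
            e -= 1
        if e - s > best[1] - best[0]:
            best = (s, e)
    return best


def _has_exact_run(mismatch: np.ndarray, start: int, end: int, k: int) -> bool:
    run = 0
    for i in range(start, end):
        run = 0 if mismatch[i] else run + 1
        if run >= k:
            return True
    return False


def scan_integration(
    candidate: str,
    genome: dict[str, str] | str,
    k: int = 31,
    min_id: float = 90.0,
    min_len: int = 100,
) -> list[GenomeHit]:
    """Find candidate/genome diagonal segments with identity >= ``min_id`` %.

    Exact ``k``-mer seeds select diagonals on both genome strands; per
    diagonal, the longest ungapped window with identity at or above the
    threshold (and containing at least one exact k-length run) is reported
    when it reaches ``min_len``.
    """
    if k < 15:
        raise ValueError("seed length k must be >= 15")
    cand = normalize_nt(candidate)
    if isinstance(genome, str):
        genome = {"genome": genome}
    if not genome or all(not s for s in genome.values()):
        raise ValueError("empty genome")
    hits: list[GenomeHit] = []
    if len(cand) < k:
        return hits
    cand_kmers: dict[str, list[int]] = {}
    for i in range(len(cand) - k + 1):
        cand_kmers.setdefault(cand[i:i + k], []).append(i)
    max_mismatch_frac = 1.0 - min_id / 100.0
    for gid in sorted(genome):
        gfwd = normalize_nt(genome[gid])
        for strand, gseq in (("+", gfwd), ("-", revcomp(gfwd))):
            diagonals: set[int] = set()
            for j in range(len(gseq) - k + 1):
                kmer = gseq[j:j + k]
                for i in cand_kmers.get(kmer, ()):
                    diagonals.add(j - i)
            g_arr = np.frombuffer(gseq.encode(), dtype=np.uint8)
            c_arr = np.frombuffer(cand.encode(), dtype=np.uint8)
            for diag in sorted(diagonals):
                c_lo = max(0, -diag)
                g_lo = c_lo + diag
                span = min(len(cand) - c_lo, len(gseq) - g_lo)
                mism = c_arr[c_lo:c_lo + span] != g_arr[g_lo:g_lo + span]
                s, e = _longest_window(mism, max_mismatch_frac)
                length = e - s
                if length < min_len or not _has_exact_run(mism, s, e, k):
                    continue
                ident = 100.0 * (1.0 - float(mism[s:e].mean()))
                cs, ce = c_lo + s, c_lo + e - 1  # 0-based on candidate
                gs, ge = g_lo + s, g_lo + e - 1  # 0-based on scanned strand
                if strand == "-":
                    gs, ge = len(gseq) - 1 - ge, len(gseq) - 1 - gs
                hits.append(GenomeHit(
                    genome_id=gid, strand=strand,
                    cand_start=cs + 1, cand_end=ce + 1,
                    genome_start=gs + 1, genome_end=ge + 1,
                    length=length, pct_identity=ident,
                ))
    hits.sort(key=lambda h: (-h.length, -h.pct_identity, h.genome_id, h.genome_start))
    return hits


def dna_read_coverage(candidate: str, dna_reads: dict[str, str], k: int = 31) -> float:
    """Fraction of candidate positions covered by a k-mer shared with any DNA read."""
    if k < 15:
        raise ValueError("seed length k must be >= 15")
    cand = normalize_nt(candidate)
    if not dna_reads:
        warnings.warn("no DNA reads supplied: coverage is 0 by construction")
        return 0.0
    read_kmers: set[str] = set()
    for r in dna_reads.values():
        r = normalize_nt(r, allow_empty=True)
        for i in range(len(r) - k + 1):
            read_kmers.add(r[i:i + k])
            # reads come from double-stranded DNA
            read_kmers.add(revcomp(r[i:i + k]))
    covered = np.zeros(len(cand), dtype=bool)
    for i in range(len(cand) - k + 1):
        if cand[i:i + k] in read_kmers:
            covered[i:i + k] = True
    return float(covered.mean()) if len(cand) else 0.0


def classify_exogenous(evidence: IntegrationEvidence, thresholds: EveThresholds | None = None) -> str:
    """Turn integration evidence into a verdict: EVE / bona_fide / ambiguous."""
    t = thresholds or EveThresholds()
    strong = [
        h for h in evidence.genome_hits
        if h.length >= t.min_len and h.pct_identity >= t.min_id
    ]
    if strong or evidence.dna_covered_fraction >= t.cov_min:
        return "EVE"
    near = [
        h for h in evidence.genome_hits
        if h.length >= t.min_len and h.pct_identity >= t.min_id - t.ambiguous_margin
    ]
    if near:
        return "ambiguous"
    return "bona_fide"
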