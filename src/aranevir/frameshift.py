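"""-1 programmed ribosomal frameshift signals: slippery heptamer + pseudoknot.

A -1 frameshift cassette consists of a heptanucleotide "slippery sequence"
of the form X_XXX_XXY (positions 1-3 one base, 4-6 one base, position 7
distinct from position 6; e.g. U_UUU_UUA as in HIV-1 and Sindbis virus, or
the astrovirus A_AAA_AAC) followed closely downstream by an H-type
pseudoknot that stalls the ribosome.  On a fraction of elongation events
the stalled ribosome backtracks one nucleotide and resumes in the -1 frame,
producing a fused ORF1a-b product.

The pseudoknot caller here is a deterministic, longest-stem-first
combinatorial search over Watson-Crick/G.U paired stems — no thermodynamic
energy model.  Stem/loop bounds are exposed in :class:`PseudoknotParams`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import can_pair, normalize_nt
from .annotate import OrfAnnotation, translate_codons

__all__ = [
    "PseudoknotParams",
    "Pseudoknot",
    "FrameshiftSite",
    "FusedProduct",
    "default_slippery_patterns",
    "find_slippery_sites",
    "detect_pseudoknot",
    "fuse_frameshift_product",
]

# The two heptamer classes reported for this virus group; more X_XXX_XXY
# heptamers can be supplied by the caller.
DEFAULT_PATTERNS = ("TTTTTTA", "AAAAAAC")


def default_slippery_patterns() -> tuple[str, ...]:
    return DEFAULT_PATTERNS


def pattern_class(heptamer: str) -> str:
    """Render a heptamer in the conventional X_XXX_XXY RNA notation."""
    h = heptamer.replace("T", "U")
    return f"{h[0]}_{h[1:4]}_{h[4:7]}"


def is_slippery(heptamer: str) -> bool:
    """True for X_XXX_XXY heptamers: 1-3 identical, 4-6 identical, 7 distinct."""
    h = heptamer
    return (
        len(h) == 7
        and h[0] == h[1] == h[2]
        and h[3] == h[4] == h[5]
        and h[6] != h[5]
    )


@dataclass(frozen=True)
class PseudoknotParams:
    """Bounds for the deterministic H-type pseudoknot search.

    ``stem1`` must begin ``s1_offset_min``..``s1_offset_max`` nt after the
    anchor (the heptamer end), span at least ``stem1_min`` pairs, enclose a
    loop of ``loop1_min``..``loop1_max`` nt, and the crossing ``stem2``
    (>= ``stem2_min`` pairs) pairs the loop1-adjacent bases with a region at
    most ``max_gap2`` nt downstream of stem1's 3' arm.
    """

    s1_offset_min: int = 5
    s1_offset_max: int = 12
    stem1_min: int = 5
    stem1_max: int = 12
    loop1_min: int = 3
    loop1_max: int = 15
    stem2_min: int = 4
    max_gap2: int = 30


@dataclass(frozen=True)
class Pseudoknot:
    """Stem coordinates (1-based inclusive (start, end) per arm) of an H-type knot."""

    stem1_5p: tuple[int, int]
    stem1_3p: tuple[int, int]
    stem2_5p: tuple[int, int]
    stem2_3p: tuple[int, int]


@dataclass
class FrameshiftSite:
    position: int  # 1-based coordinate of the heptamer start
    heptamer: str
    pattern_class: str
    pseudoknot: Pseudoknot
    fused_protein_len: int | None = None


@dataclass
class FusedProduct:
    protein: str
    truncated: bool = False
    shift_position: int | None = None  # heptamer start, if a shift occurred


def _stem_ok(s: str, arm1_start: int, arm2_start: int, length: int) -> bool:
    """Antiparallel helix check (0-based arm starts)."""
    for t in range(length):
        if not can_pair(s[arm1_start + t], s[arm2_start + length - 1 - t]):
            return False
    return True


def detect_pseudoknot(seq: str, anchor: int, params: PseudoknotParams | None = None) -> Pseudoknot | None:
    """Deterministic greedy search for an H-type pseudoknot downstream of ``anchor``.

    ``anchor`` is the 1-based coordinate of the last heptamer base.  Stems
    are searched longest-first; the first hit is returned, ``None`` if the
    3' context is too short or no knotted (crossing-stem) arrangement
    exists within the bounds.
    """
    p = params or PseudoknotParams()
    s = normalize_nt(seq)
    n = len(s)
    if not 1 <= anchor <= n:
        raise ValueError(f"anchor {anchor} outside sequence of length {n}")
    for L1 in range(p.stem1_max, p.stem1_min - 1, -1):
        for off in range(p.s1_offset_min, p.s1_offset_max + 1):
            i = anchor + off  # 0-based start of stem1 5' arm
            for loop1 in range(p.loop1_min, p.loop1_max + 1):
                j = i + L1 + loop1  # 0-based start of stem1 3' arm
                if j + L1 > n:
                    continue
                if not _stem_ok(s, i, j, L1):
                    continue
                # crossing stem2: 5' arm sits at the start of loop1,
                # 3' arm at most max_gap2 nt beyond stem1's 3' arm.
                for L2 in range(min(loop1, n), p.stem2_min - 1, -1):
                    if i + L1 + L2 > j:
                        continue
                    for gap2 in range(0, p.max_gap2 + 1):
                        d = j + L1 + gap2
                        if d + L2 > n:
                            break
                        if _stem_ok(s, i + L1, d, L2):
                            return Pseudoknot(
                                stem1_5p=(i + 1, i + L1),
                                stem1_3p=(j + 1, j + L1),
                                stem2_5p=(i + L1 + 1, i + L1 + L2),
                                stem2_3p=(d + 1, d + L2),
                            )
    return None


def find_slippery_sites(
    seq: str,
    orf1a: OrfAnnotation,
    patterns: tuple[str, ...] | None = None,
    params: PseudoknotParams | None = None,
) -> list[FrameshiftSite]:
    """Scan the final third of ``orf1a`` for slippery heptamers with a pseudoknot.

    Heptamers must match one of the X_XXX_XXY ``patterns``, sit at an
    in-frame position (the heptamer straddles a codon boundary as
    X | XXX | XXY), and be backed by a downstream H-type pseudoknot.
    Positions are 1-based heptamer starts.
    """
    if orf1a.orientation != "forward":
        raise ValueError("frameshift scan requires a forward-orientation ORF1a")
    s = normalize_nt(seq)
    pats = set(patterns or DEFAULT_PATTERNS)
    for pat in pats:
        if not is_slippery(normalize_nt(pat)):
            raise ValueError(f"pattern {pat!r} is not an X_XXX_XXY heptamer")
    span = orf1a.end - orf1a.start + 1
    region_start = orf1a.start + (2 * span) // 3  # final third of the ORF
    sites = []
    for pos in range(region_start, orf1a.end - 6 + 1):  # 1-based heptamer start
        hept = s[pos - 1:pos + 6]
        if hept not in pats:
            continue
        # X | XXX | XXY phasing: the first heptamer base ends a codon.
        if (pos - orf1a.start) % 3 != 2:
            continue
        knot = detect_pseudoknot(s, pos + 6, params)
        if knot is None:
            continue
        sites.append(FrameshiftSite(
            position=pos,
            heptamer=hept,
            pattern_class=pattern_class(hept),
            pseudoknot=knot,
        ))
    return sites


def fuse_frameshift_product(seq: str, orf1a: OrfAnnotation, site: FrameshiftSite | None) -> FusedProduct:
    """Translate the ORF1a-b fusion generated by a -1 shift at ``site``.

    Translation proceeds in the ORF1a frame through the heptamer (the codon
    ending at its 7th base), then the ribosome backtracks one nucleotide:
    the heptamer's last base is re-used as the first base of the next codon
    and translation continues in the -1 frame to the next stop.  Without a
    site the plain ORF1a product is returned.
    """
    s = normalize_nt(seq)
    orf_protein = orf1a.protein or translate_codons(s[orf1a.start - 1:orf1a.end - 3])
    if site is None:
        return FusedProduct(protein=orf_protein, truncated=False, shift_position=None)
    if not orf1a.start <= site.position <= orf1a.end - 6:
        raise ValueError("slippery site does not lie inside ORF1a")
    h7 = site.position + 6  # 1-based coordinate of the reused nucleotide
    upstream = s[orf1a.start - 1:h7]  # codons through the one ending at h7
    if len(upstream) % 3:
        raise ValueError("slippery site is out of frame with ORF1a")
    part_a = translate_codons(upstream)
    shifted = s[h7 - 1:]  # -1 frame resumes on the reused base
    part_b_full = translate_codons(shifted)
    stop = part_b_full.find("*")
    truncated = stop == -1
    part_b = part_b_full if truncated else part_b_full[:stop]
    return FusedProduct(protein=part_a + part_b, truncated=truncated, shift_position=site.position)
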