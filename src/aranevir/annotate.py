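"""ORF annotation, protein mass, UTR composition and pairwise identity.

Coordinate convention (used throughout the package and its reports): ORF
coordinates are 1-based, inclusive, given on the deposited strand, and
*include* the stop codon; the amino-acid length excludes the stop, so

    aa_length = (end - start + 1) / 3 - 1.

Reverse-orientation ORFs keep ascending deposited-strand coordinates
(start < end) and carry ``orientation="reverse"``.  This is the only
convention under which the printed coordinate/length pairs of published
virus annotations are mutually consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Align import PairwiseAligner, substitution_matrices

from ._seq import normalize_nt, revcomp

__all__ = [
    "OrfAnnotation",
    "UtrProfile",
    "CoordinateError",
    "find_orfs",
    "orf_aa_length",
    "protein_mass_kda",
    "utr_profile",
    "pairwise_identity",
]

# Average (not monoisotopic) residue masses in Da; one water (18.015 Da) is
# added per chain.  Average masses match the kDa scale used when reporting
# polyprotein sizes.
AVERAGE_RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS_DA = 18.015

_CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


def translate_codons(seq: str) -> str:
    """Translate an in-frame nucleotide string; N-containing codons give 'X'."""
    aa = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        aa.append(_CODON_TABLE.get(seq[i:i + 3], "X"))
    return "".join(aa)


class CoordinateError(ValueError):
    """Raised when printed ORF coordinates are internally inconsistent."""


@dataclass(frozen=True)
class OrfAnnotation:
    """A predicted ORF on a candidate virus sequence.

    ``start``/``end`` are 1-based inclusive deposited-strand coordinates and
    include the stop codon; ``protein`` excludes the stop.
    """

    start: int
    end: int
    orientation: str  # "forward" | "reverse"
    protein: str
    aa_length: int
    mass_kda: float

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass
class UtrProfile:
    utr5_len: int
    utr3_len: int
    uuua_count: int
    # (1-based window start, GC fraction, AU fraction) tiling the sequence
    windows: list[tuple[int, float, float]] = field(default_factory=list)


def orf_aa_length(start: int, end: int) -> int:
    """Amino-acid count of an ORF span that includes its stop codon.

    Raises :class:`CoordinateError` if the span is not a whole number of
    codons — published coordinates occasionally are, and silently rounding
    would hide the inconsistency.
    """
    if end <= start:
        raise CoordinateError(f"ORF end {end} must exceed start {start}")
    span = end - start + 1
    if span % 3:
        raise CoordinateError(
            f"ORF span {start}-{end} covers {span} nt, not divisible by 3; "
            "coordinates are internally inconsistent"
        )
    return span // 3 - 1


def protein_mass_kda(aa_seq: str) -> float:
    """Average molecular mass of a protein chain, in kDa."""
    if not aa_seq:
        raise ValueError("empty protein sequence")
    total = WATER_MASS_DA
    for res in aa_seq:
        try:
            total += AVERAGE_RESIDUE_MASS_DA[res]
        except KeyError:
            raise ValueError(f"unknown amino-acid residue {res!r}") from None
    return total / 1000.0


def _scan_frame(frame_seq: str, offset: int, min_aa: int):
    """Yield (start0, end0, protein) for maximal ATG->stop ORFs in one frame.

    Coordinates are 0-based inclusive on the scanned strand.  The maximal
    ORF per stop is reported: the first ATG after the previous in-frame stop.
    """
    atg = None
    n = len(frame_seq) - (len(frame_seq) - offset) % 3
    for pos in range(offset, n - 2, 3):
        codon = frame_seq[pos:pos + 3]
        if codon == "ATG" and atg is None:
            atg = pos
        elif _CODON_TABLE.get(codon, "X") == "*":
            if atg is not None:
                aa_len = (pos + 3 - atg) // 3 - 1
                if aa_len >= min_aa:
                    yield atg, pos + 2, translate_codons(frame_seq[atg:pos])
            atg = None


def find_orfs(seq: str, min_aa: int = 100, both_strands: bool = True) -> list[OrfAnnotation]:
    """Predict stop-terminated ATG-initiated ORFs of at least ``min_aa`` residues.

    Only complete (stop-terminated) ORFs are reported, one maximal ORF per
    in-frame stop.  Reverse-strand ORFs are mapped back to deposited-strand
    coordinates.  Results are sorted by amino-acid length, longest first.
    """
    s = normalize_nt(seq)
    n = len(s)
    orfs: list[OrfAnnotation] = []
    for offset in range(3):
        for s0, e0, prot in _scan_frame(s, offset, min_aa):
            orfs.append(_make_orf(s0 + 1, e0 + 1, "forward", prot))
    if both_strands:
        rc = revcomp(s)
        for offset in range(3):
            for s0, e0, prot in _scan_frame(rc, offset, min_aa):
                # map [s0, e0] on the reverse strand to deposited coordinates
                orfs.append(_make_orf(n - e0, n - s0, "reverse", prot))
    orfs.sort(key=lambda o: (-o.aa_length, o.start, o.orientation))
    return orfs


def _make_orf(start: int, end: int, orientation: str, protein: str) -> OrfAnnotation:
    mass = protein_mass_kda(protein) if protein and "X" not in protein else float("nan")
    return OrfAnnotation(
        start=start,
        end=end,
        orientation=orientation,
        protein=protein,
        aa_length=orf_aa_length(start, end),
        mass_kda=mass,
    )


def utr_profile(seq: str, orfs: list[OrfAnnotation], window: int = 100, step: int = 10) -> UtrProfile:
    """Composition profile of a candidate genome and its untranslated regions.

    The 5'UTR runs from position 1 to one base before the first ORF start;
    ``uuua_count`` counts (overlapping) UUUA motifs within it — the loop
    motif typical of picornaviral IRES-bearing 5'UTRs.  Windows of fixed
    width tile the whole sequence for GC/AU line graphs.
    """
    if not orfs:
        raise ValueError("utr_profile requires at least one ORF")
    s = normalize_nt(seq)
    first = min(o.start for o in orfs)
    last = max(o.end for o in orfs)
    utr5 = s[: first - 1]
    count = 0
    idx = utr5.find("TTTA")
    while idx != -1:
        count += 1
        idx = utr5.find("TTTA", idx + 1)
    windows = []
    for pos in range(0, len(s) - window + 1, step):
        win = s[pos:pos + window]
        gc = (win.count("G") + win.count("C")) / window
        au = (win.count("A") + win.count("T")) / window
        windows.append((pos + 1, gc, au))
    return UtrProfile(
        utr5_len=first - 1,
        utr3_len=len(s) - last,
        uuua_count=count,
        windows=windows,
    )


def _global_aligner(level: str) -> PairwiseAligner:
    aligner = PairwiseAligner()
    aligner.mode = "global"
    if level == "nt":
        aligner.match_score = 1.0
        aligner.mismatch_score = -1.0
        aligner.open_gap_score = -2.0
        aligner.extend_gap_score = -2.0
    elif level == "aa":
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = -11.0
        aligner.extend_gap_score = -1.0
    else:
        raise ValueError(f"level must be 'nt' or 'aa', got {level!r}")
    return aligner


def pairwise_identity(seq_a: str, seq_b: str, level: str = "nt") -> float:
    """Percent identity of the optimal global alignment of two sequences.

    Nucleotide scoring is match +1 / mismatch -1 / gap -2; protein scoring is
    BLOSUM62 with gap open 11, extend 1.  Identity is the fraction of
    alignment columns (gaps included in the denominator) that are identical.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_identity requires non-empty sequences")
    if level == "nt":
        seq_a, seq_b = normalize_nt(seq_a), normalize_nt(seq_b)
    aln = _global_aligner(level).align(seq_a, seq_b)[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length
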