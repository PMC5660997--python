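"""Small shared nucleotide-sequence helpers.

All public entry points normalise RNA input (U -> T, case-folded) so that the
rest of the package works on a single DNA-letter internal representation.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

NT_ALPHABET = frozenset("ACGTN")

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})

# Watson-Crick plus the G.U (G.T in DNA letters) wobble pair, RNA context.
_PAIRED = frozenset({("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")})


def normalize_nt(seq: str, *, allow_empty: bool = False) -> str:
    """Uppercase, map U->T and validate against {A,C,G,T,N}."""
    s = seq.upper().replace("U", "T")
    if not s and not allow_empty:
        raise ValueError("empty nucleotide sequence")
    bad = set(s) - NT_ALPHABET
    if bad:
        raise ValueError(f"invalid nucleotide symbol(s): {sorted(bad)}")
    return s


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def can_pair(a: str, b: str, allow_gu: bool = True) -> bool:
    """True if bases a, b form a Watson-Crick (or, optionally, G.U wobble) pair."""
    if not allow_gu and {a, b} == {"G", "T"}:
        return False
    return (a, b) in _PAIRED


def pair_type(a: str, b: str) -> str:
    """'WC' or 'GU' for a paired base combination."""
    if {a, b} == {"G", "T"}:
        return "GU"
    return "WC"
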