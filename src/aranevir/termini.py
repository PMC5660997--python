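"""Genome-termini complementarity (panhandle) and simplified RNA folding.

Negative-sense RNA virus segments carry quasi-complementary 5' and 3'
termini that base-pair into a double-stranded "panhandle", the replication
promoter.  :func:`panhandle_duplex` scores that complementarity with a
gap-free sliding model that counts Watson-Crick and G.U pairs — a declared
simplification of cofolding energy models; the "extends over N nt"
reporting level stays checkable.

:func:`nussinov_fold` is exact base-pair-maximisation folding (Nussinov
dynamic programming) for short elements such as 3'UTR stem-loop arrays.
It maximises pair count, not free energy: stem-loop counts are reported
descriptively with no claim of thermodynamic MFE equivalence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._seq import can_pair, normalize_nt, pair_type

__all__ = ["PanhandleResult", "panhandle_duplex", "FoldResult", "nussinov_fold"]

MAX_FOLD_LEN = 300


@dataclass
class PanhandleResult:
    """Terminal complementarity of one genome segment.

    ``duplex_len`` is the length of the longest terminal region pairable
    without any mismatch run longer than the configured maximum;
    ``paired_fraction`` is the fraction of positions inside that region
    that actually pair.  ``pairs`` lists (5' position, 3' position, 'WC'|'GU'),
    both 1-based within the supplied termini, 3' positions counted on the
    three-prime terminus string.
    """

    duplex_len: int
    paired_fraction: float
    offset: int
    pairs: list[tuple[int, int, str]] = field(default_factory=list)


def _anchored_region(
    match: np.ndarray, max_mismatch_run: int, min_paired: float, max_skip: int
) -> tuple[int, int]:
    """Longest terminally-anchored window over a match mask.

    The window must begin within the first ``max_skip + 1`` positions
    (duplexes nucleate at the genome ends), start and end on a paired
    position, contain no mismatch run longer than ``max_mismatch_run``,
    and keep a paired fraction of at least ``min_paired``.  Returns
    (start, length), (0, 0) if none qualifies.
    """
    n = len(match)
    cum = np.concatenate(([0], np.cumsum(match)))
    best = (0, 0)
    for i in range(min(max_skip + 1, n)):
        if not match[i]:
            continue
        run = 0
        for j in range(i, n):
            if match[j]:
                run = 0
                length = j - i + 1
                if length > best[1] and (cum[j + 1] - cum[i]) / length >= min_paired:
                    best = (i, length)
            else:
                run += 1
                if run > max_mismatch_run:
                    break
    return best


def panhandle_duplex(
    five_term: str,
    three_term: str,
    w: int = 40,
    max_mismatch_run: int = 2,
    min_paired_fraction: float = 0.85,
    max_offset: int = 4,
    max_terminal_skip: int = 2,
    allow_gu: bool = True,
) -> PanhandleResult:
    """Score 5'/3' terminal complementarity by gap-free sliding.

    The first ``w`` nt of the 5' terminus are slid (no gaps, offsets up to
    ``max_offset`` for small terminal overhangs) against the last ``w`` nt
    of the 3' terminus read 3'->5', pairing antiparallel positions that are
    Watson-Crick or G.U complementary.  The reported duplex is the longest
    region that (a) begins within ``max_terminal_skip`` bases of the
    molecule ends — panhandles nucleate at the termini — (b) contains no
    mismatch run longer than ``max_mismatch_run``, and (c) stays at least
    ``min_paired_fraction`` paired; ties prefer the smallest offset.  Under
    these constraints random termini essentially never reach duplexes of
    promoter-like length.
    """
    x = normalize_nt(five_term)[:w]
    y = normalize_nt(three_term)[-w:]
    if min(len(x), len(y)) < 10:
        warnings.warn("terminal window shorter than 10 nt: panhandle call is degenerate")
    three_len = len(normalize_nt(three_term))
    z = y[::-1]  # 3' terminus read 3'->5'; z[k] is three_term position three_len - k
    best: tuple[int, float, int, int] | None = None  # ranking key
    best_payload = None
    for off in range(-max_offset, max_offset + 1):
        # x[i] aligns with z[i - off]
        lo = max(0, off)
        hi = min(len(x), len(z) + off)
        if hi - lo < 1:
            continue
        match = np.fromiter(
            (can_pair(x[i], z[i - off], allow_gu) for i in range(lo, hi)), bool, hi - lo
        )
        start, length = _anchored_region(match, max_mismatch_run, min_paired_fraction, max_terminal_skip)
        if length == 0:
            continue
        frac = float(match[start:start + length].mean())
        key = (-length, -frac, abs(off), off)
        if best is None or key < best:
            best = key
            best_payload = (off, lo + start, length, match[start:start + length])
    if best_payload is None:
        return PanhandleResult(duplex_len=0, paired_fraction=0.0, offset=0, pairs=[])
    off, start_i, length, match = best_payload
    pairs = []
    for t in range(length):
        i = start_i + t
        if match[t]:
            k = i - off
            pairs.append((i + 1, three_len - k, pair_type(x[i], z[k])))
    return PanhandleResult(
        duplex_len=length,
        paired_fraction=float(match.mean()),
        offset=off,
        pairs=pairs,
    )


@dataclass
class FoldResult:
    structure: str  # Vienna dot-bracket
    n_pairs: int
    stem_loops: int  # number of hairpin loops
    pairs: list[tuple[int, int]] = field(default_factory=list)  # 1-based


def nussinov_fold(seq: str, min_loop: int = 3) -> FoldResult:
    """Maximum-base-pair nested folding of a short RNA (<= 300 nt).

    Exact dynamic programming over Watson-Crick + G.U pairs with hairpin
    loops of at least ``min_loop`` unpaired bases, and a deterministic
    traceback (pairing preferred, then leftmost decomposition).  Longer
    inputs are refused: use a thermodynamic folding tool for those.
    """
    s = normalize_nt(seq)
    n = len(s)
    if n > MAX_FOLD_LEN:
        raise ValueError(
            f"sequence of {n} nt exceeds the {MAX_FOLD_LEN} nt limit of exact "
            "pair-maximisation folding; use a dedicated RNA folding tool"
        )
    M = np.zeros((n + 1, n + 1), dtype=np.int32)  # M[i, j] on 0-based [i, j] inclusive
    pairable = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + min_loop + 1, n):
            pairable[i, j] = can_pair(s[i], s[j])
    for span in range(min_loop + 1, n):
        for i in range(0, n - span):
            j = i + span
            best = M[i, j - 1]  # j unpaired
            if pairable[i, j]:
                best = max(best, M[i + 1, j - 1] + 1)
            # bifurcation i..k | k+1..j (k = i also covers "i unpaired")
            bif = int((M[i, i:j] + M[i + 1:j + 1, j]).max())
            M[i, j] = max(best, bif)
    pairs: list[tuple[int, int]] = []
    stack = [(0, n - 1)] if n else []
    while stack:
        i, j = stack.pop()
        if j - i < min_loop + 1:
            continue
        if pairable[i, j] and M[i, j] == M[i + 1, j - 1] + 1:
            pairs.append((i, j))
            stack.append((i + 1, j - 1))
            continue
        if M[i, j] == M[i, j - 1]:
            stack.append((i, j - 1))
            continue
        for k in range(i, j):
            if M[i, j] == M[i, k] + M[k + 1, j]:
                stack.append((i, k))
                stack.append((k + 1, j))
                break
    pairs.sort()
    structure = ["."] * n
    for i, j in pairs:
        structure[i], structure[j] = "(", ")"
    dot = "".join(structure)
    stem_loops = _count_hairpins(dot)
    return FoldResult(
        structure=dot,
        n_pairs=len(pairs),
        stem_loops=stem_loops,
        pairs=[(i + 1, j + 1) for i, j in pairs],
    )


def _count_hairpins(dot: str) -> int:
    """Hairpin loops: '(' followed by ')' with only dots between."""
    count = 0
    last_open = -1
    for idx, c in enumerate(dot):
        if c == "(":
            last_open = idx
        elif c == ")":
            if last_open != -1:
                count += 1
            last_open = -1
    return count
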