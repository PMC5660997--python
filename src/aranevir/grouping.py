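"""Group candidate viral segments into putative multipartite viruses.

Segments of one multipartite virus rise and fall together: they are present
in exactly the same libraries and their RNA levels co-vary across libraries.
Grouping therefore requires (a) identical presence/absence patterns and
(b) pairwise Pearson correlation of log2(FPKM + 1), over the libraries of
the shared pattern, at or above ``r_min`` for *every* pair in a group
(complete linkage, so one promiscuous segment cannot chain unrelated
viruses).  Everything else stays a singleton.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VirusGroup", "presence_matrix", "group_segments"]

#: minimum libraries in a shared presence pattern before co-expression is
#: considered statistically meaningful
MIN_PRESENT_LIBRARIES = 3


@dataclass
class VirusGroup:
    group_id: str
    members: list[str]
    presence_pattern: tuple[str, ...]  # library ids where members are present
    mean_pairwise_r: float
    flagged: str | None = None  # e.g. "single_library", "sparse_pattern"


def presence_matrix(
    fpkm: pd.DataFrame,
    counts: pd.DataFrame,
    fpkm_min: float = 1.0,
    frag_min: int = 10,
) -> pd.DataFrame:
    """Presence calls: present iff FPKM >= fpkm_min AND fragments >= frag_min."""
    if not (fpkm.shape == counts.shape and fpkm.index.equals(counts.index)
            and fpkm.columns.equals(counts.columns)):
        raise ValueError("fpkm and counts matrices must share shape and labels")
    return (fpkm >= fpkm_min) & (counts >= frag_min)


def _pairwise_r(log_fpkm: pd.DataFrame, a: str, b: str, libs: list[str]) -> float:
    x = log_fpkm.loc[a, libs].to_numpy(dtype=float)
    y = log_fpkm.loc[b, libs].to_numpy(dtype=float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def group_segments(
    fpkm: pd.DataFrame,
    counts: pd.DataFrame,
    r_min: float = 0.8,
    fpkm_min: float = 1.0,
    frag_min: int = 10,
) -> list[VirusGroup]:
    """Partition segments (rows) into co-expression groups.

    Deterministic greedy complete-linkage within each presence-pattern
    class, seeds taken in lexicographic segment-id order.  With a single
    library, grouping is refused (singletons flagged ``single_library``);
    patterns present in fewer than three libraries cannot support a
    correlation and also stay singletons (``sparse_pattern``).
    """
    presence = presence_matrix(fpkm, counts, fpkm_min, frag_min)
    if fpkm.shape[1] < 2:
        return [
            VirusGroup(f"G{i + 1:03d}", [seg], _pattern(presence, seg), float("nan"),
                       flagged="single_library")
            for i, seg in enumerate(sorted(fpkm.index))
        ]
    log_fpkm = np.log2(fpkm + 1.0)
    by_pattern: dict[tuple[str, ...], list[str]] = {}
    for seg in sorted(fpkm.index):
        by_pattern.setdefault(_pattern(presence, seg), []).append(seg)

    groups: list[VirusGroup] = []
    for pattern in sorted(by_pattern):
        members = by_pattern[pattern]
        libs = list(pattern)
        if len(libs) < MIN_PRESENT_LIBRARIES:
            flag = "sparse_pattern" if libs else "all_absent"
            for seg in members:
                groups.append(VirusGroup("", [seg], pattern, float("nan"), flagged=flag))
            continue
        unassigned = list(members)
        while unassigned:
            seed = unassigned.pop(0)
            group = [seed]
            rest = []
            for seg in unassigned:
                if all(_pairwise_r(log_fpkm, seg, m, libs) >= r_min for m in group):
                    group.append(seg)
                else:
                    rest.append(seg)
            unassigned = rest
            if len(group) > 1:
                rs = [
                    _pairwise_r(log_fpkm, group[i], group[j], libs)
                    for i in range(len(group)) for j in range(i + 1, len(group))
                ]
                mean_r = float(np.mean(rs))
            else:
                mean_r = float("nan")
            groups.append(VirusGroup("", group, pattern, mean_r))
    # stable ids: larger groups first, then by first member
    groups.sort(key=lambda g: (-len(g.members), g.members[0]))
    for i, g in enumerate(groups):
        g.group_id = f"G{i + 1:03d}"
    return groups


def _pattern(presence: pd.DataFrame, seg: str) -> tuple[str, ...]:
    row = presence.loc[seg]
    return tuple(c for c in presence.columns if bool(row[c]))


def groups_table(groups: list[VirusGroup]) -> pd.DataFrame:
    """Long-format table (group_id, segment_id, n_members, pattern, mean_r, flag)."""
    rows = []
    for g in groups:
        for seg in g.members:
            rows.append({
                "group_id": g.group_id,
                "segment_id": seg,
                "n_members": len(g.members),
                "pattern": ";".join(g.presence_pattern),
                "mean_r": g.mean_pairwise_r,
                "flag": g.flagged or "",
            })
    return pd.DataFrame(rows)
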