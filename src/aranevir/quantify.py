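"""Host-normalized virus RNA quantification.

Virus RNA levels are expressed as Fragments Per Kilobase of virus
transcript per Million mapped reads (FPKM), where the "million" counts
non-rRNA host transcriptome reads that map to the host genome assembly —
not total library reads:

    FPKM = fragments / ((length_nt / 1e3) * (host_mapped_reads / 1e6))

Host normalization avoids the diluting effect of variable non-host read
levels (other viruses, incomplete rRNA depletion) on between-library
comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["fpkm", "fpkm_table", "TissueSummary", "summarize_profiles", "plot_fpkm_heatmap"]


def fpkm(fragments, length_nt, host_mapped_reads):
    """FPKM of a segment in one library; vectorises over numpy/pandas inputs."""
    length_nt = np.asarray(length_nt, dtype=float)
    host = np.asarray(host_mapped_reads, dtype=float)
    if np.any(length_nt <= 0):
        raise ValueError("segment length must be positive")
    if np.any(host <= 0):
        raise ValueError("host_mapped_reads must be positive")
    out = np.asarray(fragments, dtype=float) / ((length_nt / 1e3) * (host / 1e6))
    return out if out.ndim else float(out)


def fpkm_table(counts: pd.DataFrame, lengths: pd.Series, host_mapped_reads: pd.Series) -> pd.DataFrame:
    """FPKM matrix from a fragment-count matrix (rows: segments, cols: libraries)."""
    missing = counts.index.difference(lengths.index)
    if len(missing):
        raise ValueError(f"no length for segment(s): {list(missing)[:5]}")
    missing = counts.columns.difference(host_mapped_reads.index)
    if len(missing):
        raise ValueError(f"no host-mapped read total for library(ies): {list(missing)[:5]}")
    L = lengths.loc[counts.index].to_numpy(dtype=float)[:, None]
    H = host_mapped_reads.loc[counts.columns].to_numpy(dtype=float)[None, :]
    vals = counts.to_numpy(dtype=float) / ((L / 1e3) * (H / 1e6))
    return pd.DataFrame(vals, index=counts.index, columns=counts.columns)


@dataclass
class TissueSummary:
    tissue_mean_fpkm: pd.DataFrame  # rows: virus (or segment), cols: tissue
    individual_mean_fpkm: pd.DataFrame
    pct_viral_reads: pd.Series  # per library, percent of fragments that are viral
    total_viral_fragments: pd.Series  # per virus, absolute totals over libraries


def summarize_profiles(
    counts: pd.DataFrame,
    lengths: pd.Series,
    designs: list,
    viral_ids: set[str],
    segment_to_virus: dict[str, str] | None = None,
) -> TissueSummary:
    """Per-tissue / per-individual FPKM means and viral read fractions.

    ``counts`` holds all transcripts (host and viral); ``designs`` is the
    library design list carrying tissue/individual labels and host-mapped
    read totals.  ``segment_to_virus`` aggregates segment rows to viruses
    (identity mapping when omitted).
    """
    design_ids = {d.library_id for d in designs}
    unknown = [c for c in counts.columns if c not in design_ids]
    if unknown:
        raise ValueError(f"libraries without design metadata: {unknown[:5]}")
    designs = [d for d in designs if d.library_id in counts.columns]
    host_reads = pd.Series({d.library_id: d.host_mapped_reads for d in designs})
    tissue = pd.Series({d.library_id: d.tissue for d in designs})
    individual = pd.Series({d.library_id: d.individual for d in designs})

    viral = counts.loc[[i for i in counts.index if i in viral_ids]]
    fp = fpkm_table(viral, lengths, host_reads)
    seg2vir = segment_to_virus or {s: s for s in viral.index}
    virus_of = pd.Series({s: seg2vir.get(s, s) for s in viral.index})

    # per-virus FPKM per library: mean over its segments (levels are shared
    # per segment by construction of the normalization)
    virus_fpkm = fp.groupby(virus_of).mean()
    tissue_mean = virus_fpkm.T.groupby(tissue).mean().T
    indiv_mean = virus_fpkm.T.groupby(individual).mean().T

    viral_frags = viral.sum(axis=0)
    host_frags = counts.drop(index=viral.index).sum(axis=0)
    denom = viral_frags + host_frags
    pct = 100.0 * viral_frags / denom.where(denom > 0, other=np.nan)
    totals = viral.groupby(virus_of).sum().sum(axis=1)
    return TissueSummary(
        tissue_mean_fpkm=tissue_mean,
        individual_mean_fpkm=indiv_mean,
        pct_viral_reads=pct,
        total_viral_fragments=totals,
    )


def plot_fpkm_heatmap(fpkm_df: pd.DataFrame, path: str) -> None:
    """Optional log-scale FPKM heatmap (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(max(6, 0.45 * fpkm_df.shape[1]),
                                    max(3, 0.3 * fpkm_df.shape[0])))
    im = ax.imshow(np.log2(fpkm_df.to_numpy(dtype=float) + 1.0), aspect="auto", cmap="viridis")
    ax.set_xticks(range(fpkm_df.shape[1]), fpkm_df.columns, rotation=90, fontsize=6)
    ax.set_yticks(range(fpkm_df.shape[0]), fpkm_df.index, fontsize=6)
    fig.colorbar(im, ax=ax, label="log2(FPKM + 1)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
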