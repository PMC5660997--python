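"""File-format helpers: FASTA (via Biopython), hit TSV, ORF GFF3."""

from __future__ import annotations

from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotate import OrfAnnotation
from .search import TranslatedHit

HIT_COLUMNS = [
    "transcript_id", "frame", "t_start", "t_end", "reference_id",
    "r_start", "r_end", "score", "evalue", "pct_identity",
]


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | Path) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def hits_to_frame(hits: list[TranslatedHit]) -> pd.DataFrame:
    return pd.DataFrame([h.to_row() for h in hits], columns=HIT_COLUMNS)


def write_hits_tsv(hits: list[TranslatedHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_orfs_gff3(orfs_by_seq: dict[str, list[OrfAnnotation]], path: str | Path) -> None:
    """GFF3 CDS features; attributes carry aa_length and mass_kda."""
    lines = ["##gff-version 3"]
    for seq_id in sorted(orfs_by_seq):
        for i, orf in enumerate(orfs_by_seq[seq_id], start=1):
            strand = "+" if orf.orientation == "forward" else "-"
            attrs = (
                f"ID={seq_id}.orf{i};aa_length={orf.aa_length};"
                f"mass_kda={orf.mass_kda:.3f}"
            )
            lines.append(
                "\t".join([
                    seq_id, "aranevir", "CDS", str(orf.start), str(orf.end),
                    ".", strand, "0", attrs,
                ])
            )
    Path(path).write_text("\n".join(lines) + "\n")
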