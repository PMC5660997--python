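"""Annotate a candidate virus genome: ORFs, protein mass, UTR composition.

Coordinates are 1-based inclusive and include the stop codon, so a span of
N codons encodes N-1 amino acids — the convention under which published
virus ORF tables are internally consistent.
"""

from aranevir import build_dataset, default_config, find_orfs, utr_profile

ds = build_dataset(default_config(), seed=1)
seg = next(s for s in ds.truth.segments if s.virus == "picorna_like")
seq = ds.transcripts[seg.transcript_id]

orfs = find_orfs(seq, min_aa=100)
print(f"picorna-like genome ({len(seq)} nt), {len(orfs)} ORF(s):")
for o in orfs:
    print(f"  {o.start}-{o.end} ({o.orientation}): {o.aa_length} aa polyprotein, "
          f"{o.mass_kda:.1f} kDa")

prof = utr_profile(seq, orfs, window=100, step=10)
utr_au = [au for pos, gc, au in prof.windows if pos + 99 <= prof.utr5_len]
print(f"\n5'UTR: {prof.utr5_len} nt, mean AU fraction "
      f"{sum(utr_au) / len(utr_au):.2f}, {prof.uuua_count} UUUA motifs")
print("(long AU-rich 5'UTRs with UUUA loops are the hallmark of IRES-bearing")
print(" picornaviral genomes; translation initiates cap-independently)")
print(f"3'UTR: {prof.utr3_len} nt")
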