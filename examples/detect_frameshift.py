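"""Find a -1 programmed ribosomal frameshift and build the fused product.

The scan looks for X_XXX_XXY slippery heptamers in the final third of
ORF1a, requires a downstream H-type pseudoknot (the stalling element), and
translates the ORF1a-b fusion: through the heptamer in frame 0, then the
heptamer's last base is re-used as the ribosome backtracks one nucleotide.
"""

from aranevir import build_dataset, default_config, find_orfs, find_slippery_sites, fuse_frameshift_product

ds = build_dataset(default_config(), seed=1)
seg = next(s for s in ds.truth.segments if s.slippery)
seq = ds.transcripts[seg.transcript_id]

orf1a = [o for o in find_orfs(seq, min_aa=100) if o.orientation == "forward"][0]
print(f"astro-like genome ({len(seq)} nt); ORF1a {orf1a.start}-{orf1a.end} "
      f"({orf1a.aa_length} aa)")

(site,) = find_slippery_sites(seq, orf1a)
k = site.pseudoknot
print(f"slippery site {site.pattern_class} at position {site.position} "
      f"(planted at {seg.slippery['position']})")
print(f"pseudoknot stems: {k.stem1_5p}..{k.stem1_3p} crossed by {k.stem2_5p}..{k.stem2_3p}")

fused = fuse_frameshift_product(seq, orf1a, site)
print(f"fused ORF1a-b product: {len(fused.protein)} aa "
      f"(ORF1a alone: {orf1a.aa_length} aa; planted: {seg.slippery['fused_protein_len']} aa)")
print("-1 frameshifting lets one genome express the replicase as a C-terminal")
print("extension of ORF1a at a fixed stoichiometry set by shift efficiency.")
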