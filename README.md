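# aranevir

RNA virome discovery and characterization from transcriptome assemblies.

Metatranscriptomic surveys of arthropods routinely uncover deeply divergent
RNA viruses: a transcript assembly is screened by translated homology
against known viral proteins, candidate genomes are annotated and checked
for the structural hallmarks of their lineages, multipartite genome
segments are reassembled from co-expression, endogenous viral elements
(EVEs) are excluded against the host genome, and virus RNA levels are
profiled across tissues.  `aranevir` packages that whole analysis path as a
tested Python library — with a thin `aranevir` command-line wrapper — for
people who study invertebrate (here, spider-flavored) viromes or who need a
fully controlled synthetic benchmark for virome-discovery methods.

Because real surveys operate on millions of transcripts and public
databases, the package ships a first-class synthetic-data module: it
generates a 16-library, 4-individual tissue survey with planted viruses
covering the architectures the pipeline must handle, plus a
machine-readable truth record, so every claim the pipeline makes can be
scored against ground truth.

## The methods at the core

**Discovery.** Each transcript is translated in all six frames; every frame
is aligned locally against each reference protein (Smith–Waterman,
BLOSUM62, gap open 11 / extend 1; stop codons never align).  A hit is kept
when its Karlin–Altschul expectation

E = K·m·n·e^(−λS),  with ungapped BLOSUM62 constants K = 0.041, λ = 0.267,

falls below 1e-5 (m = frame length, n = total database residues).  Scores
are exact for the scoring scheme — there is no word-seeding heuristic — but
E-values are an approximation, not bit-compatible with NCBI BLAST.

**Annotation.** ORF coordinates are 1-based, inclusive, and include the
stop codon, so `aa_length = (end − start + 1)/3 − 1`; this is the only
convention under which published virus ORF tables are internally
consistent.  Protein masses use average residue masses plus one water.
UTR composition (GC/AU windows, UUUA motif counts) profiles the long
AU-rich 5'UTRs of IRES-bearing picorna-like genomes.

**Structural signals.** A −1 programmed ribosomal frameshift is called
when an X_XXX_XXY slippery heptamer (e.g. U_UUU_UUA) in the final third of
ORF1a is backed by a downstream H-type pseudoknot (deterministic
longest-stem-first search over WC/G·U pairs); the fused ORF1a-b product
re-uses the heptamer's seventh base.  Panhandle promoters of negative-sense
segments are scored as the longest terminally-anchored gap-free duplex
between the genome ends; short UTR elements are folded by exact Nussinov
pair maximisation.

**Grouping, EVE screen, quantification.** Segments join one multipartite
virus only if they share an identical presence/absence pattern across
libraries and every pair correlates at Pearson r ≥ 0.8 on log2(FPKM+1)
(complete linkage).  Candidates with a ≥ 100 nt, ≥ 90 % identity ungapped
hit on the host genome — or ≥ 10 % DNA-read k-mer coverage — are flagged
EVE; clean candidates are bona fide viruses.  RNA levels are

FPKM = fragments / ((segment length / 10³) · (host-mapped reads / 10⁶)),

normalized by *host-genome-mapped* (non-rRNA) reads so that levels stay
comparable when libraries differ in non-host content.

## Worked example

```bash
$ aranevir run --seed 1 --outdir out/
15 candidates; report at out/report.json
```

or, from Python (`examples/run_full_pipeline.py`):

```text
stage counts: {'search': {'transcripts': 75, 'hits': 15, 'candidates': 15},
 'annotate': {'candidates': 15, 'orfs': 15},
 'group': {'groups': 5, 'multi': 2},
 'eve': {'candidates': 15, 'eve': 1},
 'quantify': {'viruses': 15}}

15 candidates; 1 flagged EVE; 2 multipartite groups (10/2 segments)
frameshift on tr00037: U_UUU_UUA at 1200, fused product 614 aa
```

Reading: of 75 transcripts, exactly the 15 planted viral segments pass the
E ≤ 1e-5 screen (no host false positives).  Co-expression reassembles the
10-segment reo-like and the bipartite bunya-like virus; the planted
endogenous element is the one candidate flagged EVE; and the astro-like
candidate carries a U_UUU_UUA slippery site at position 1200 whose −1
fusion product is 614 aa — all matching `out/simulated/truth.json`.
The other examples (`examples/*.py`) each exercise one capability and
print what the numbers mean.

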