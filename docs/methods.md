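# Methods

This note documents the models, conventions and numerical choices behind
`aranevir`, what the synthetic benchmark does and does not emulate, and the
known limitations of each component.

## Translated homology search

Discovery follows the TBLASTN idea without its heuristics: all six reading
frames of every transcript are aligned locally against every reference
protein with the exact affine-gap Smith–Waterman optimum (BLOSUM62; a gap
of length k costs 11 + (k−1)·1).  Stop codons appear as `*` in the frames
and receive a −10⁶ substitution score against everything, which confines
local alignments to stop-free stretches without splitting sequences.

Significance uses the Karlin–Altschul formula E = K·m·n·e^(−λS) with the
*ungapped* BLOSUM62 constants K = 0.041, λ = 0.267, m the translated frame
length and n the summed database residues, with no length or
composition corrections.  This is a deliberate simplification: the filter
is monotone-correct in the score (doubling the database doubles E; E is
strictly decreasing in S) but not bit-compatible with NCBI BLAST, and the
threshold (default 1e-5) is exposed so users can re-calibrate against
their own null.  Per (transcript, reference) pair only the best-scoring
frame is reported.  Redundancy collapse keeps, per transcript, a set of
hits whose pairwise span overlap is at most 50 % of the shorter span,
preferring lower E-value, then higher score, then lexicographic reference
id; the procedure is idempotent.

There is no word-seeding, two-hit logic, HSP chaining across frames, or
profile search; on desk-scale inputs the exhaustive alignment is fast
enough (a full benchmark screen takes a few seconds), and exactness is
what the oracle tests certify.

## ORF annotation conventions

Coordinates are 1-based, inclusive, on the deposited strand, and include
the stop codon: `aa_length = (end − start + 1)/3 − 1`.  Published virus
ORF tables are checkable under exactly this convention, and the package
refuses (with `CoordinateError`) printed spans that are not a whole number
of codons rather than rounding silently — one published pair
(722–7,226, reported as 2,412 aa) is internally inconsistent in just this
way.  Reverse-orientation ORFs keep ascending deposited-strand coordinates
with an orientation flag.

The finder reports only ATG-initiated, stop-terminated ORFs, one maximal
ORF per in-frame stop (the first ATG after the previous stop), on both
strands by default, sorted longest-first; `min_aa` defaults to 100 for
discovery.  Alternative start codons are off.  Protein masses are average
(not monoisotopic) residue masses plus one water of 18.015 Da — the scale
on which polyprotein sizes are conventionally reported in kDa.

UTR profiling defines the 5'UTR as positions 1 to one base before the
first ORF start, counts overlapping UUUA motifs there, and tiles the whole
genome with 100 nt windows every 10 nt for GC/AU line graphs (the window
is a display resolution, not a statistical choice).

Global pairwise identity (nucleotide: match +1/mismatch −1/gap −2;
protein: BLOSUM62, gaps 11/1) is reported as identical columns over all
alignment columns, gaps included.  When several alignments are co-optimal
the first deterministic traceback is used; the test suite checks the
reported identity against exhaustive alignment enumeration on short pairs.

## −1 frameshift signals

A site is called when (a) a heptamer from the configured template set
(default U_UUU_UUA and A_AAA_AAC; any X_XXX_XXY heptamer may be added)
lies in the final third of ORF1a at the in-frame phase X | XXX | XXY, and
(b) an H-type pseudoknot follows.  The pseudoknot search is a
deterministic, longest-stem-first combinatorial scan: stem 1 (5–12 pairs)
must begin 5–12 nt after the heptamer, enclose a 3–15 nt loop, and be
crossed by stem 2 (≥ 4 pairs) pairing loop-adjacent bases with a region at
most 30 nt beyond stem 1's 3' arm; Watson–Crick and G·U both pair.  There
is no thermodynamic model — KnotInFrame-style energy ranking is out of
scope — so the caller certifies topology (crossing stems), not stability,
and all bounds are exposed in `PseudoknotParams`.

The fused ORF1a-b product translates through the codon ending at the
heptamer's seventh base, then re-uses that base as the ribosome backtracks
one nucleotide and continues in the −1 frame to the next stop; a missing
−1 stop yields a truncated-product flag rather than an error.

## Genome termini

The panhandle scorer slides the first w nt of a segment (default 40)
gap-free against its last w nt read 3'→5', pairing antiparallel positions
(WC + G·U).  The reported duplex is the longest region that begins within
2 nt of the molecule ends, contains no mismatch run longer than 2, and
stays ≥ 85 % paired, over offsets up to ±4 nt.  The terminal anchoring and
paired-fraction floor are essential, not cosmetic: with unbounded sliding
and only the mismatch-run bound, random 40-mer termini yield median
"duplexes" of ~24 nt (6/16 base combinations pair once G·U is allowed),
destroying the contrast the statistic exists to report.  Under the
anchored definition random termini stay below 10 nt in ≈ 99 % of draws
while engineered 32 nt complementary termini score 32 — so "extends over
30 nt" remains a meaningful promoter-level statement.  Pair counting
replaces cofolding energies by design; no melting or ensemble claim is
made.  One caveat: because G·U is not closed under complementation, the
duplex is *not* exactly invariant under swapping termini and
reverse-complementing both (the vRNA and cRNA panhandles genuinely differ
at wobble positions); the exact invariance holds under WC-only pairing
(`allow_gu=False`).

Short elements (≤ 300 nt) are folded by exact Nussinov dynamic programming
(maximum WC+G·U pairs, hairpin loops ≥ 3 nt, deterministic traceback that
prefers pairing, then the leftmost decomposition).  Pair maximisation
cannot see loop entropies, so adjacent hairpins with cross-pairable stems
are often reported as one nested structure; stem-loop counts therefore
describe the maximum-pair structure, not the thermodynamic ensemble, and
longer inputs are refused with a pointer to dedicated folding tools.

## Multipartite grouping

Presence in a library requires FPKM ≥ 1 *and* ≥ 10 fragments (the
fragment floor keeps length-normalisation from promoting a handful of
reads on a short segment).  Segments group only if their presence patterns
are identical with at least three present libraries — Pearson correlation
over fewer points is not evidence — and every member pair correlates at
r ≥ 0.8 on log2(FPKM+1) over the pattern's libraries.  Complete linkage is
deliberate: one promiscuous segment cannot chain two viruses.  Groups are
built greedily in lexicographic segment order, which makes the output
deterministic and order-independent; raising r_min can only refine a
grouping, never merge groups.  With a single library the operation refuses
and returns flagged singletons.  All thresholds (1 FPKM, 10 fragments,
r = 0.8) are declared substitutes for a verbal "significant co-expression"
criterion and are exposed in the configuration.

## EVE screening

Integration evidence combines (a) ungapped genome hits: exact 31-mer seeds
select candidate/genome diagonals on both strands, and per diagonal the
longest window with identity ≥ the threshold (and containing an exact
31 nt run) is reported when ≥ 100 nt; and (b) the fraction of candidate
positions covered by 31-mers shared with host DNA reads (both read
strands).  Verdicts: EVE on a ≥ 90 % identity hit or ≥ 10 % DNA coverage;
ambiguous when the best qualifying hit falls within 5 identity points
below the cutoff; bona fide otherwise.  The identity/length/coverage
thresholds are declared substitutes for a BLASTN E-value rule and are
config-exposed.  Extension is ungapped by design, so an integrated copy
fragmented by indels would surface as several shorter hits; breakpoint
reconstruction is out of scope.  The window definition is exactly mirrored
by a naive sliding-window oracle in the tests.

## Quantification

FPKM = fragments / ((length/10³)·(host-mapped reads/10⁶)), with the
denominator restricted to non-rRNA reads mapping to the host genome.
Normalising by host-mapped rather than total reads keeps levels comparable
when libraries differ in viral load or non-host content (a high-titer
library would otherwise dilute itself).  Fragments are used as provided
(pairs counted once); there is no effective-length correction.  Summaries
report per-virus per-tissue and per-individual mean FPKM, per-library
percent viral fragments (viral / (viral + host), valid because libraries
are rRNA-free by construction), and absolute per-virus totals.

## The synthetic benchmark

`default_config()` plants, against 60 random host transcripts
(300–1,500 nt) and a 60 kb random host genome:

| model | architecture | sizes | hallmark |
|---|---|---|---|
| picorna_like | monopartite polyprotein | 2,800 nt | 760 nt 5'UTR at AU fraction 0.7 |
| bunya_like | bipartite, reverse ORFs | 2,400 + 1,600 nt | 32 nt complementary termini |
| reo_like | 10 segments | 600–1,500 nt | shared presence/co-expression |
| astro_like | frameshift fusion | 2,200 nt | U_UUU_UUA + pseudoknot cassette, 614 aa fusion |
| eve_like | monopartite | 1,200 nt | diverged copy (5 % substitutions) integrated in the genome |

Genome sizes are scaled to roughly a quarter of their real counterparts so
that the exhaustive search, the full pipeline and the five-replicate
acceptance run complete in seconds to minutes; every architectural feature
the pipeline tests for is kept at realistic magnitude (the 760 nt UTR and
32 nt panhandle are real-scale).  Reference proteins are the planted ORF
products point-substituted to a 40 % target amino-acid identity — the
middle of the identity range such surveys report for best hits — with the
realized identity re-verified by global alignment and recorded in the
truth record.

Segments are rejection-sampled until the package's own annotators recover
exactly the planted truth (no spurious ≥ 100 aa ORFs, no upstream in-frame
ATG extending a planted ORF, exactly one slippery site at the planted
position with the planted fusion length).  This makes truth-recovery tests
measure the discovery code rather than generator noise; it also means the
benchmark cannot measure robustness to ambiguous annotations, which real
data have.

The frameshift cassette downstream of the heptamer is T-free
(stems GGCGGC/GCCGCC and GGGG/CCCC, loops of A/C), so it can introduce no
stop codon in any reading frame; the ORF1b continuation is generated
directly on the −1 codon grid, stop- and ATG-free, ending in a planted
stop 232 codons past the shift.

Libraries follow the 16-isolate design (2 whole-body, 2 brain, 10 silk,
2 venom across 4 individuals).  Each virus infects a fixed subset of
individuals; all libraries of an infected individual carry all its
segments.  Per-library abundance scales (expected FPKM) are drawn
log2-uniformly over [2³, 2¹⁵] per virus and library — tissue surveys
report viral FPKM spanning orders of magnitude, and the wide spread is
also what makes co-expression statistically identifiable over the negative
binomial noise floor.  Fragment counts are negative binomial with
var = μ + 0.2 μ² (dispersion α = 0.2, the quadratic/edgeR convention; the
paper-level sources give no noise model) and mean
abundance × segment_kb × host_reads/10⁶, so a segment's expected FPKM
equals its abundance scale by construction — the basis of the
parameter-recovery test (mean FPKM over 200 replicate libraries within
10 % at mean counts ≥ 500).  Host counts get independent per-library
lognormal noise, so host transcripts do not co-vary the way virus segments
do.  Host-mapped read totals are ~10⁷ per library, a scaled-down stand-in
for survey-scale depth that keeps counts in a realistic regime.

What the generator does **not** emulate: reads (counts are simulated
directly; mapping, strand bleed-through and multi-mapping do not exist
here), sequencing error and quality scores, rRNA carryover, assembly
chimerism/fragmentation, shared k-mer content between host transcripts and
the host genome, and polymorphism among individuals.  Passing the
benchmark therefore demonstrates the correctness of the discovery logic
under its stated model, not robustness to the artifacts of real
assemblies.

## Determinism and degenerate inputs

Everything stochastic flows from a single seeded `numpy` generator; a
fixed (config, seed) reproduces byte-identical FASTA/TSV/JSON outputs, and
the pipeline report is identical across reruns up to stage timings.
Empty transcript sets yield a valid empty report; an empty reference
database, empty sequences, non-codon ORF spans, unknown residues and
out-of-range parameters raise immediately with the offending value named.
Ties are broken deterministically throughout (alignment traceback order,
lowest E-value then score then reference id in redundancy collapse,
lexicographic seeds in grouping, smallest offset in panhandle scoring).
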