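"""Synthetic virome benchmark generator with machine-readable ground truth.

The generator emulates the structure of a spider transcriptome virome
survey: 16 RNA libraries from 4 individuals over whole-body / brain / silk
/ venom tissues, a host transcript background, and planted viruses covering
the architectures the discovery pipeline must handle —

* a monopartite polyprotein virus with a long AU-rich 5'UTR (picorna-like),
* a bipartite negative-sense virus with reverse-orientation ORFs and >30 nt
  complementary genome termini (bunya-like panhandle),
* a 10-segment dsRNA virus (reo-like),
* a monopartite virus expressing a fused ORF1a-b product via a -1
  frameshift at a U_UUU_UUA slippery site backed by an H-type pseudoknot
  (astro-like),
* optionally an endogenous viral element: a virus-like transcript whose
  (diverged) copy is integrated in the host genome.

Every planted feature is recorded in a :class:`TruthRecord`; segments are
rejection-sampled until the package's own annotators recover exactly the
planted truth, so truth recovery tests measure the discovery code, not
generator noise.  Libraries are rRNA-free by construction: the FPKM
denominator (host-genome-mapped read total) is part of the library design,
and fragment *counts* — not reads — are simulated, from a negative binomial
with var = mu + alpha * mu^2.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import STOP_CODONS, revcomp
from .annotate import find_orfs, pairwise_identity, translate_codons
from .frameshift import find_slippery_sites

__all__ = [
    "VirusModel",
    "LibraryDesign",
    "TruthRecord",
    "GeneratorConfig",
    "Dataset",
    "default_config",
    "default_library_designs",
    "build_dataset",
    "plant_eve",
    "simulate_library_counts",
]

NT = np.array(list("ACGT"))
_NONSTOP_CODONS = sorted(
    {a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"} - STOP_CODONS
)
# codons excluded when a reading frame must stay both stop-free and ATG-free
_PLAIN_CODONS = sorted(set(_NONSTOP_CODONS) - {"ATG"})
_AA20 = "ACDEFGHIKLMNPQRSTVWY"

ARCHITECTURES = ("monopartite_polyprotein", "multipartite", "frameshift_fusion")
TISSUES = ("whole_body", "brain", "silk", "venom")


class ConfigurationError(ValueError):
    """A virus model or generator configuration violates its invariants."""


@dataclass(frozen=True)
class VirusModel:
    """Declarative description of one virus to plant.

    ``orf_layout`` holds, per segment, (start, end, orientation) triples in
    the package's ORF coordinate convention (1-based inclusive, stop codon
    inside the span).  ``utr5_len``/``au_bias`` shape the 5'UTR of the
    first segment; ``panhandle_len`` > 0 engineers complementary termini on
    every segment; ``slippery_site`` plants a -1 frameshift cassette
    (heptamer + H-type pseudoknot) in the final third of the first ORF.
    """

    name: str
    architecture: str
    segment_lengths: tuple[int, ...]
    orf_layout: tuple[tuple[tuple[int, int, str], ...], ...]
    utr5_len: int = 0
    au_bias: float = 0.5
    panhandle_len: int = 0
    slippery_site: str | None = None  # heptamer, e.g. "TTTTTTA"
    pseudoknot: bool = True

    def validate(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ConfigurationError(f"unknown architecture {self.architecture!r}")
        if len(self.segment_lengths) != len(self.orf_layout):
            raise ConfigurationError(f"{self.name}: one ORF layout per segment required")
        for L, orfs in zip(self.segment_lengths, self.orf_layout):
            for start, end, orient in orfs:
                if (end - start + 1) % 3:
                    raise ConfigurationError(
                        f"{self.name}: ORF span {start}-{end} not a whole number of codons"
                    )
                if not (1 <= start < end <= L):
                    raise ConfigurationError(f"{self.name}: ORF {start}-{end} exceeds segment of {L} nt")
                if orient not in ("forward", "reverse"):
                    raise ConfigurationError(f"{self.name}: bad orientation {orient!r}")
                if self.panhandle_len and (start <= self.panhandle_len or end > L - self.panhandle_len):
                    raise ConfigurationError(f"{self.name}: ORF overlaps engineered termini")
        if self.panhandle_len and self.panhandle_len >= min(self.segment_lengths) / 2:
            raise ConfigurationError(f"{self.name}: panhandle_len must be < shortest segment / 2")
        if not 0.0 <= self.au_bias <= 1.0:
            raise ConfigurationError(f"{self.name}: au_bias must lie in [0, 1]")
        if self.architecture == "frameshift_fusion" and not self.slippery_site:
            raise ConfigurationError(f"{self.name}: frameshift_fusion requires a slippery_site")


@dataclass
class LibraryDesign:
    library_id: str
    individual: str
    tissue: str
    host_mapped_reads: int
    infection_status: dict[str, bool] = field(default_factory=dict)
    abundance_scale: dict[str, float] = field(default_factory=dict)  # FPKM-like

    def validate(self) -> None:
        if self.host_mapped_reads <= 0:
            raise ConfigurationError(f"{self.library_id}: host_mapped_reads must be > 0")
        if self.tissue not in TISSUES:
            raise ConfigurationError(f"{self.library_id}: unknown tissue {self.tissue!r}")


@dataclass
class SegmentTruth:
    segment_id: str
    virus: str
    transcript_id: str
    length: int
    orfs: list[dict]  # start, end, orientation, aa_length
    panhandle_len: int = 0
    slippery: dict | None = None  # position, heptamer, fused_protein_len


@dataclass
class EveInsertion:
    segment_id: str
    genome_id: str
    start: int  # 1-based inclusive insertion span in the modified genome
    end: int
    divergence: float
    realized_identity: float


@dataclass
class TruthRecord:
    """Everything the generator planted, fully determined by (config, seed)."""

    seed: int
    segments: list[SegmentTruth] = field(default_factory=list)
    reference_proteins: dict[str, dict] = field(default_factory=dict)
    eve_insertions: list[EveInsertion] = field(default_factory=list)
    expected_counts: dict[str, dict[str, float]] = field(default_factory=dict)

    def viruses(self) -> dict[str, list[SegmentTruth]]:
        out: dict[str, list[SegmentTruth]] = {}
        for seg in self.segments:
            out.setdefault(seg.virus, []).append(seg)
        return out

    def viral_transcript_ids(self) -> set[str]:
        return {seg.transcript_id for seg in self.segments}

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True)


@dataclass
class GeneratorConfig:
    viruses: tuple[VirusModel, ...]
    n_host_transcripts: int = 60
    host_len_range: tuple[int, int] = (300, 1500)
    ref_target_identity: float = 0.40  # aa identity of reference proteins
    nb_dispersion: float = 0.2  # alpha in var = mu + alpha mu^2
    host_genome_len: int = 60_000
    plant_eve: bool = True
    eve_divergence: float = 0.05
    dna_read_len: int = 100
    dna_read_step: int = 50
    orf_check_min_aa: int = 100  # planted truth must be exactly recoverable here
    host_reads_range: tuple[int, int] = (8_000_000, 12_000_000)
    abundance_log2_range: tuple[float, float] = (3.0, 15.0)
    host_log2_fpkm_mean: float = 4.0
    host_log2_fpkm_sd: float = 2.0
    host_library_noise_sd: float = 1.0  # independent per (transcript, library)

    def validate(self) -> None:
        if not self.viruses:
            raise ConfigurationError("config must name at least one VirusModel")
        for v in self.viruses:
            v.validate()


def _reo_layout(lengths: tuple[int, ...]) -> tuple:
    layout = []
    for L in lengths:
        end = 30 + 3 * ((L - 60) // 3)
        layout.append(((31, end, "forward"),))
    return tuple(layout)


def default_config() -> GeneratorConfig:
    """The default benchmark: four exogenous viruses plus one EVE-like element.

    Genome sizes are desk-scale (0.6-2.8 kb) while keeping the architecture
    hallmarks: the 760 nt AU-rich 5'UTR, 32 nt complementary termini,
    ten co-expressed segments, and a U_UUU_UUA frameshift cassette.
    """
    reo_lengths = (1500, 1450, 1250, 1150, 1000, 950, 850, 750, 650, 600)
    viruses = (
        VirusModel(
            name="picorna_like", architecture="monopartite_polyprotein",
            segment_lengths=(2800,), orf_layout=(((761, 2563, "forward"),),),
            utr5_len=760, au_bias=0.7,
        ),
        VirusModel(
            name="bunya_like", architecture="multipartite",
            segment_lengths=(2400, 1600),
            orf_layout=(((56, 2305, "reverse"),), ((51, 1430, "reverse"),)),
            utr5_len=0, panhandle_len=32,
        ),
        VirusModel(
            name="reo_like", architecture="multipartite",
            segment_lengths=reo_lengths, orf_layout=_reo_layout(reo_lengths),
            utr5_len=30,
        ),
        VirusModel(
            name="astro_like", architecture="frameshift_fusion",
            segment_lengths=(2200,), orf_layout=(((61, 1263, "forward"),),),
            utr5_len=60, au_bias=0.55, slippery_site="TTTTTTA",
        ),
        VirusModel(
            name="eve_like", architecture="monopartite_polyprotein",
            segment_lengths=(1200,), orf_layout=(((31, 1140, "forward"),),),
            utr5_len=30,
        ),
    )
    return GeneratorConfig(viruses=viruses)


# ---------------------------------------------------------------------------
# sequence synthesis


def _random_nt(rng: np.random.Generator, n: int, au: float = 0.5) -> np.ndarray:
    p = np.array([au / 2, (1 - au) / 2, (1 - au) / 2, au / 2])  # A C G T
    return rng.choice(NT, size=n, p=p)


def _random_codons(rng: np.random.Generator, n: int, codons=None) -> str:
    pool = codons or _NONSTOP_CODONS
    return "".join(rng.choice(pool, size=n))


def _fill_forward_orf(rng: np.random.Generator, arr: np.ndarray, start: int, end: int) -> None:
    n_codons = (end - start + 1) // 3
    orf = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
    arr[start - 1:end] = list(orf)


def _fill_reverse_orf(rng: np.random.Generator, arr: np.ndarray, start: int, end: int) -> None:
    n_codons = (end - start + 1) // 3
    orf = "ATG" + _random_codons(rng, n_codons - 2) + "TAA"
    arr[start - 1:end] = list(revcomp(orf))


# -1 frameshift cassette layout, relative to the heptamer start p (1-based):
#   p..p+6        slippery heptamer (X_XXX_XXY)
#   p+7..p+11     spacer ACACA
#   p+12..p+17    stem1 5' arm  GGCGGC
#   p+18..p+23    loop1         GGGGAA (first four bases = stem2 5' arm)
#   p+24..p+29    stem1 3' arm  GCCGCC
#   p+30..p+31    gap           CA
#   p+32..p+35    stem2 3' arm  CCCC
# The cassette is T-free downstream of the heptamer, so it introduces no
# stop codon in any reading frame.
_CASSETTE = "ACACA" + "GGCGGC" + "GGGGAA" + "GCCGCC" + "CA" + "CCCC"
CASSETTE_LEN = 7 + len(_CASSETTE)  # 36 nt including the heptamer
_FS_TAIL_CODONS = 8  # 0-frame codons between cassette end and the ORF1a stop
_FS_SHIFT_CODONS = 232  # -1 frame codons of the fused product past the shift


def _build_frameshift_segment(rng: np.random.Generator, model: VirusModel):
    """Build the frameshift segment; returns (seq, orf_truth, slippery_truth)."""
    L = model.segment_lengths[0]
    (start, end, orient), = model.orf_layout[0]
    if orient != "forward":
        raise ConfigurationError(f"{model.name}: ORF1a must be forward")
    hept = model.slippery_site.upper().replace("U", "T")
    # heptamer start: in X|XXX|XXY phase and leaving room for cassette + tail
    p = end - 3 - 3 * _FS_TAIL_CODONS - CASSETTE_LEN + 1
    while (p - start) % 3 != 2:
        p -= 1
    span = end - start + 1
    if p < start + (2 * span) // 3:
        raise ConfigurationError(f"{model.name}: ORF1a too short for a final-third cassette")
    h7 = p + 6
    n_shift_stop = h7 + 3 * _FS_SHIFT_CODONS  # 1-based start of the -1 frame stop codon
    if n_shift_stop + 2 > L - 10:
        raise ConfigurationError(f"{model.name}: segment too short for the ORF1b continuation")

    arr = _random_nt(rng, L)
    if model.utr5_len:
        arr[: model.utr5_len] = _random_nt(rng, model.utr5_len, model.au_bias)
    _fill_forward_orf(rng, arr, start, end)
    arr[p - 1:p + 6] = list(hept)
    arr[p + 6:p + 6 + len(_CASSETTE)] = list(_CASSETTE)
    # 0-frame codons between cassette and stop must also be stop-free in the
    # -1 frame (the fused product reads through them)
    for _ in range(200):
        tail = _random_codons(rng, _FS_TAIL_CODONS)
        arr[end - 3 - 3 * _FS_TAIL_CODONS:end - 3] = list(tail)
        minus1 = "".join(arr[h7 - 1:end])
        if "*" not in translate_codons(minus1):
            break
    else:  # pragma: no cover - rejection loop exhausted
        raise RuntimeError("could not make the overlap region stop-free in the -1 frame")
    # ORF1b continuation on the -1 frame grid: stop-free and ATG-free (the
    # product exists only as a fusion), terminated by TAA.  The -1 grid has a
    # codon starting on ORF1a's last base ('A??', never a stop); regeneration
    # starts with the first grid codon fully past ORF1a.
    resume = end + 3  # (end - h7) % 3 == 0, so this is on the -1 codon grid
    n_free = (n_shift_stop - resume) // 3
    arr[resume - 1:n_shift_stop - 1] = list(_random_codons(rng, n_free, _PLAIN_CODONS))
    arr[n_shift_stop - 1:n_shift_stop + 2] = list("TAA")
    fused_len = (h7 - start + 1) // 3 + _FS_SHIFT_CODONS
    slippery = {
        "position": p,
        "heptamer": hept,
        "fused_protein_len": fused_len,
        "shift_stop": n_shift_stop,
    }
    return "".join(arr), [(start, end, "forward")], slippery


def _build_plain_segment(rng: np.random.Generator, model: VirusModel, idx: int):
    L = model.segment_lengths[idx]
    orfs = model.orf_layout[idx]
    arr = _random_nt(rng, L)
    if idx == 0 and model.utr5_len:
        arr[: model.utr5_len] = _random_nt(rng, model.utr5_len, model.au_bias)
    for start, end, orient in orfs:
        if orient == "forward":
            _fill_forward_orf(rng, arr, start, end)
        else:
            _fill_reverse_orf(rng, arr, start, end)
    if model.panhandle_len:
        w = model.panhandle_len
        arr[L - w:] = list(revcomp("".join(arr[:w])))
    return "".join(arr), [(s, e, o) for s, e, o in orfs], None


def _segment_ok(seq: str, orf_truth, slippery, min_aa: int) -> bool:
    """The package's own annotators must recover exactly the planted truth."""
    found = {(o.start, o.end, o.orientation) for o in find_orfs(seq, min_aa=min_aa)}
    if found != set(orf_truth):
        return False
    if slippery is not None:
        from .frameshift import fuse_frameshift_product

        orf1a = [o for o in find_orfs(seq, min_aa=min_aa) if o.orientation == "forward"][0]
        sites = find_slippery_sites(seq, orf1a)
        if len(sites) != 1 or sites[0].position != slippery["position"]:
            return False
        fused = fuse_frameshift_product(seq, orf1a, sites[0])
        if fused.truncated or len(fused.protein) != slippery["fused_protein_len"]:
            return False
    return True


def _synthesize_segment(rng: np.random.Generator, model: VirusModel, idx: int, min_aa: int):
    for _ in range(300):
        if model.architecture == "frameshift_fusion" and idx == 0:
            seq, orf_truth, slippery = _build_frameshift_segment(rng, model)
        else:
            seq, orf_truth, slippery = _build_plain_segment(rng, model, idx)
        if _segment_ok(seq, orf_truth, slippery, min_aa):
            return seq, orf_truth, slippery
    raise RuntimeError(
        f"{model.name} segment {idx}: could not synthesize a segment whose "
        "annotation matches the planted truth (layout may be too permissive)"
    )


def _mutate_protein(rng: np.random.Generator, protein: str, target_identity: float) -> str:
    """Point-substitute a protein down to the target global identity."""
    n = len(protein)
    n_mut = int(round((1.0 - target_identity) * n))
    pos = rng.choice(n, size=n_mut, replace=False)
    out = list(protein)
    for i in pos:
        choices = [a for a in _AA20 if a != out[i]]
        out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


# ---------------------------------------------------------------------------
# library design and counts


def default_library_designs(
    rng: np.random.Generator,
    virus_names: list[str],
    host_reads_range=(8_000_000, 12_000_000),
    abundance_log2_range=(3.0, 15.0),
) -> list[LibraryDesign]:
    """The 16-library, 4-individual default design.

    Two whole-body, two brain, ten silk and two venom libraries across four
    individuals; each virus infects a fixed subset of individuals and all
    libraries of an infected individual carry it.  Per-library abundance
    scales (expected FPKM) are drawn log2-uniformly over a wide range —
    viral loads in tissue surveys span orders of magnitude.
    """
    layout = [
        ("wb_1", "F1", "whole_body"),
        ("wb_2", "F2", "whole_body"),
        ("brain_1", "F3", "brain"),
        ("brain_2", "F4", "brain"),
        ("venom_1", "F3", "venom"),
        ("venom_2", "F4", "venom"),
    ]
    layout += [(f"silk_{i + 1}", "F3" if i < 5 else "F4", "silk") for i in range(10)]
    infected_individuals = {
        "picorna_like": {"F1", "F2", "F3", "F4"},
        "bunya_like": {"F3", "F4"},
        "reo_like": {"F2", "F3", "F4"},
        "astro_like": {"F1", "F3", "F4"},
        "eve_like": {"F1", "F2", "F3", "F4"},
    }
    lo, hi = abundance_log2_range
    designs = []
    for lib_id, indiv, tissue in layout:
        infection, abundance = {}, {}
        for v in virus_names:
            inf = indiv in infected_individuals.get(v, set(["F3", "F4"]))
            infection[v] = inf
            abundance[v] = float(2.0 ** rng.uniform(lo, hi)) if inf else 0.0
        designs.append(LibraryDesign(
            library_id=lib_id, individual=indiv, tissue=tissue,
            host_mapped_reads=int(rng.integers(*host_reads_range)),
            infection_status=infection, abundance_scale=abundance,
        ))
    for d in designs:
        d.validate()
    return designs


def _nb_sample(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative binomial with var = mu + dispersion * mu^2 (Poisson at 0)."""
    mean = np.asarray(mean, dtype=float)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    if dispersion <= 0:
        out[pos] = rng.poisson(mean[pos])
        return out
    size = 1.0 / dispersion
    p = size / (size + mean[pos])
    out[pos] = rng.negative_binomial(size, p)
    return out


def simulate_library_counts(
    truth: TruthRecord,
    designs: list[LibraryDesign],
    seed: int,
    dispersion: float = 0.2,
) -> pd.DataFrame:
    """Simulate viral fragment counts (rows: segment transcript ids, cols: libraries).

    The per-library mean is abundance_scale * (segment_kb * host_mapped
    reads / 1e6), so the expected FPKM of a segment equals its abundance
    scale by construction.  Uninfected libraries get exactly zero; all
    segments of one virus share the library's infection status.
    """
    rng = np.random.default_rng(seed)
    virus_names = {seg.virus for seg in truth.segments}
    for d in designs:
        d.validate()
        missing = virus_names - set(d.infection_status)
        if missing:
            raise ConfigurationError(f"{d.library_id}: no infection status for {sorted(missing)}")
    rows = []
    index = []
    for seg in truth.segments:
        kb = seg.length / 1e3
        means = np.array([
            (d.abundance_scale.get(seg.virus, 0.0) if d.infection_status[seg.virus] else 0.0)
            * kb * (d.host_mapped_reads / 1e6)
            for d in designs
        ])
        rows.append(_nb_sample(rng, means, dispersion))
        index.append(seg.transcript_id)
        truth.expected_counts[seg.transcript_id] = {
            d.library_id: float(m) for d, m in zip(designs, means)
        }
    return pd.DataFrame(
        np.vstack(rows) if rows else np.zeros((0, len(designs)), dtype=np.int64),
        index=index, columns=[d.library_id for d in designs],
    )


def _host_counts(
    rng: np.random.Generator,
    host_lengths: dict[str, int],
    designs: list[LibraryDesign],
    cfg: GeneratorConfig,
) -> pd.DataFrame:
    """Host background counts: independent per-library expression noise.

    Each transcript has a baseline log2 FPKM; per-(transcript, library)
    lognormal noise is independent, so host transcripts do not co-vary the
    way segments of one virus do.
    """
    ids = sorted(host_lengths)
    base = rng.normal(cfg.host_log2_fpkm_mean, cfg.host_log2_fpkm_sd, size=len(ids))
    noise = rng.normal(0.0, cfg.host_library_noise_sd, size=(len(ids), len(designs)))
    kb = np.array([host_lengths[t] / 1e3 for t in ids])[:, None]
    host_m = np.array([d.host_mapped_reads / 1e6 for d in designs])[None, :]
    means = (2.0 ** (base[:, None] + noise)) * kb * host_m
    counts = _nb_sample(rng, means, cfg.nb_dispersion)
    return pd.DataFrame(counts, index=ids, columns=[d.library_id for d in designs])


# ---------------------------------------------------------------------------
# EVE planting


def plant_eve(
    host_genome: str,
    segment: str,
    divergence: float,
    seed: int,
    genome_id: str = "genome",
    segment_id: str = "segment",
) -> tuple[str, EveInsertion]:
    """Insert a diverged copy of ``segment`` into ``host_genome``.

    The genome grows by exactly the segment length; substitutions are
    applied at the given per-base rate (no indels), and the realized
    identity of the inserted copy is recorded.
    """
    if not 0.0 <= divergence <= 0.3:
        raise ValueError("divergence must lie in [0, 0.3]")
    if len(segment) > len(host_genome):
        raise ValueError("segment longer than host genome")
    rng = np.random.default_rng(seed)
    seg = np.array(list(segment))
    n_sub = rng.binomial(len(seg), divergence)
    pos = rng.choice(len(seg), size=n_sub, replace=False)
    for i in pos:
        others = [b for b in "ACGT" if b != seg[i]]
        seg[i] = others[rng.integers(3)]
    insert_at = int(rng.integers(0, len(host_genome) + 1))
    diverged = "".join(seg)
    new_genome = host_genome[:insert_at] + diverged + host_genome[insert_at:]
    record = EveInsertion(
        segment_id=segment_id,
        genome_id=genome_id,
        start=insert_at + 1,
        end=insert_at + len(diverged),
        divergence=divergence,
        realized_identity=100.0 * (1.0 - n_sub / len(seg)),
    )
    return new_genome, record


# ---------------------------------------------------------------------------
# top-level dataset assembly


@dataclass
class Dataset:
    config: GeneratorConfig
    seed: int
    transcripts: dict[str, str]  # all transcripts, host and viral, neutral ids
    host_ids: list[str]
    reference_proteins: dict[str, str]
    truth: TruthRecord
    designs: list[LibraryDesign]
    counts: pd.DataFrame  # all transcripts x libraries
    host_genome: str
    dna_reads: dict[str, str]

    @property
    def viral_ids(self) -> set[str]:
        return self.truth.viral_transcript_ids()

    def segment_lengths(self) -> pd.Series:
        return pd.Series({t: len(s) for t, s in self.transcripts.items()})

    def segment_to_virus(self) -> dict[str, str]:
        return {seg.transcript_id: seg.virus for seg in self.truth.segments}

    def write(self, outdir: str | Path) -> None:
        from . import io as _io

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        _io.write_fasta(self.transcripts, out / "transcripts.fasta")
        _io.write_fasta(self.reference_proteins, out / "reference_proteins.faa")
        _io.write_fasta({"genome": self.host_genome}, out / "host_genome.fasta")
        _io.write_fasta(self.dna_reads, out / "dna_reads.fasta")
        self.counts.to_csv(out / "counts.tsv", sep="\t", index_label="transcript_id")
        (out / "truth.json").write_text(self.truth.to_json())
        pd.DataFrame([
            {
                "library_id": d.library_id, "individual": d.individual,
                "tissue": d.tissue, "host_mapped_reads": d.host_mapped_reads,
                **{f"infected:{v}": d.infection_status[v] for v in sorted(d.infection_status)},
                **{f"abundance:{v}": d.abundance_scale[v] for v in sorted(d.abundance_scale)},
            }
            for d in self.designs
        ]).to_csv(out / "library_design.tsv", sep="\t", index=False)


def build_dataset(config: GeneratorConfig | None = None, seed: int = 1) -> Dataset:
    """Generate the full synthetic benchmark for one seed.

    Deterministic for fixed (config, seed): sequences, library designs,
    counts and the truth record are all drawn from one seeded generator.
    """
    cfg = config or default_config()
    cfg.validate()
    rng = np.random.default_rng(seed)
    truth = TruthRecord(seed=seed)

    # 1. virus segments + reference proteins
    viral_seqs: dict[str, str] = {}
    ref_proteins: dict[str, str] = {}
    for model in cfg.viruses:
        for idx in range(len(model.segment_lengths)):
            seq, orf_truth, slippery = _synthesize_segment(rng, model, idx, cfg.orf_check_min_aa)
            seg_id = f"{model.name}_s{idx + 1:02d}"
            viral_seqs[seg_id] = seq
            orfs = find_orfs(seq, min_aa=cfg.orf_check_min_aa)
            truth.segments.append(SegmentTruth(
                segment_id=seg_id, virus=model.name, transcript_id="",
                length=len(seq),
                orfs=[{"start": o.start, "end": o.end, "orientation": o.orientation,
                       "aa_length": o.aa_length} for o in orfs],
                panhandle_len=model.panhandle_len,
                slippery=slippery,
            ))
            # one reference protein per segment: the longest planted product,
            # point-mutated down to the configured aa identity
            protein = orfs[0].protein
            ref = _mutate_protein(rng, protein, cfg.ref_target_identity)
            ref_id = f"ref_{seg_id}"
            ref_proteins[ref_id] = ref
            truth.reference_proteins[ref_id] = {
                "source_segment": seg_id,
                "target_identity": 100.0 * cfg.ref_target_identity,
                "realized_identity": pairwise_identity(protein, ref, level="aa"),
            }

    # 2. host transcripts (no planted viral content)
    host_seqs = {
        f"host_{i + 1:04d}": "".join(_random_nt(rng, int(rng.integers(*cfg.host_len_range))))
        for i in range(cfg.n_host_transcripts)
    }

    # 3. neutral transcript ids over the shuffled pool
    pool = sorted(host_seqs) + sorted(viral_seqs)
    order = rng.permutation(len(pool))
    transcripts: dict[str, str] = {}
    assigned: dict[str, str] = {}
    for rank, k in enumerate(order):
        tid = f"tr{rank + 1:05d}"
        src = pool[k]
        transcripts[tid] = host_seqs.get(src) or viral_seqs[src]
        assigned[src] = tid
    host_ids = sorted(assigned[h] for h in host_seqs)
    for seg in truth.segments:
        seg.transcript_id = assigned[seg.segment_id]

    # 4. host genome (+ optional EVE copy of the designated element)
    genome = "".join(_random_nt(rng, cfg.host_genome_len))
    if cfg.plant_eve:
        eve_segs = [s for s in truth.segments if s.virus == "eve_like"] or truth.segments[:1]
        for seg in eve_segs:
            genome, record = plant_eve(
                genome, viral_seqs[seg.segment_id], cfg.eve_divergence,
                seed=int(rng.integers(2 ** 31)), segment_id=seg.segment_id,
            )
            truth.eve_insertions.append(record)

    # 5. DNA "reads": exact tiling substrings of the final genome
    dna_reads = {
        f"read_{i + 1:06d}": genome[p:p + cfg.dna_read_len]
        for i, p in enumerate(range(0, len(genome) - cfg.dna_read_len + 1, cfg.dna_read_step))
    }

    # 6. library designs and the fragment-count table
    designs = default_library_designs(
        rng, [m.name for m in cfg.viruses], cfg.host_reads_range, cfg.abundance_log2_range,
    )
    viral_counts = simulate_library_counts(
        truth, designs, seed=int(rng.integers(2 ** 31)), dispersion=cfg.nb_dispersion,
    )
    host_lengths = {assigned[h]: len(s) for h, s in host_seqs.items()}
    host_counts = _host_counts(rng, host_lengths, designs, cfg)
    counts = pd.concat([host_counts, viral_counts]).loc[sorted(transcripts)]

    return Dataset(
        config=cfg, seed=seed, transcripts=transcripts, host_ids=host_ids,
        reference_proteins=ref_proteins, truth=truth, designs=designs,
        counts=counts, host_genome=genome, dna_reads=dna_reads,
    )
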