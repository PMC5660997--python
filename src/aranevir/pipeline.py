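"""End-to-end virome discovery pipeline.

Stages, in order: simulate (or load) inputs -> translated search ->
redundancy collapse -> ORF annotation -> frameshift & panhandle signals ->
co-expression grouping -> EVE screening -> host-normalized quantification
-> consolidated JSON report.  Deterministic for a fixed (config, seed);
every stage writes its outputs before the next starts, so a failed run
leaves partial results behind.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as _io
from .annotate import find_orfs, utr_profile
from .eve import EveThresholds, IntegrationEvidence, classify_exogenous, dna_read_coverage, scan_integration
from .frameshift import find_slippery_sites, fuse_frameshift_product
from .grouping import group_segments, groups_table
from .quantify import fpkm_table, summarize_profiles
from .search import collapse_hits, search
from .synth import Dataset, GeneratorConfig, build_dataset, default_config
from .termini import panhandle_duplex

log = logging.getLogger("aranevir")

__all__ = ["PipelineConfig", "PipelineReport", "run_pipeline", "run_on_dataset"]


@dataclass
class PipelineConfig:
    """All stage parameters in one place (YAML-loadable).

    With ``simulate=True`` the synthetic benchmark is generated in-run;
    otherwise the four input paths must point at existing files.
    """

    seed: int = 1
    outdir: str = "aranevir_out"
    simulate: bool = True
    # file inputs (used when simulate is False)
    transcripts: str | None = None
    protein_db: str | None = None
    counts: str | None = None
    library_design: str | None = None
    host_genome: str | None = None
    dna_reads: str | None = None
    # stage parameters (defaults mirror the per-module defaults)
    max_evalue: float = 1e-5
    min_orf_aa: int = 100
    panhandle_window: int = 40
    panhandle_max_mismatch_run: int = 2
    fpkm_min: float = 1.0
    frag_min: int = 10
    r_min: float = 0.8
    eve_k: int = 31
    eve_min_id: float = 90.0
    eve_min_len: int = 100
    eve_cov_min: float = 0.1

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in cls.__dataclass_fields__.values()}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def digest(self) -> str:
        payload = json.dumps(self.__dict__, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class PipelineReport:
    config_hash: str
    seed: int
    candidates: dict[str, dict] = field(default_factory=dict)
    groups: list[dict] = field(default_factory=list)
    stage_timings: dict[str, float] = field(default_factory=dict)
    stage_counts: dict[str, dict] = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=1, sort_keys=True, default=float)


@dataclass
class PipelineInputs:
    """File-loaded inputs; duck-type compatible with :class:`~aranevir.synth.Dataset`."""

    transcripts: dict[str, str]
    reference_proteins: dict[str, str]
    counts: "pd.DataFrame"
    designs: list
    host_genome: str | None = None
    dna_reads: dict[str, str] = field(default_factory=dict)

    def segment_lengths(self):
        import pandas as pd

        return pd.Series({t: len(s) for t, s in self.transcripts.items()})


def load_inputs(cfg: PipelineConfig) -> PipelineInputs:
    """Assemble pipeline inputs from the file paths in the config."""
    import pandas as pd

    from .synth import LibraryDesign

    for name in ("transcripts", "protein_db", "counts", "library_design"):
        path = getattr(cfg, name)
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"required input {name!r} missing: {path}")
    counts = pd.read_csv(cfg.counts, sep="\t", index_col=0)
    design_df = pd.read_csv(cfg.library_design, sep="\t")
    designs = []
    for _, row in design_df.iterrows():
        infection = {
            c.split(":", 1)[1]: bool(row[c]) for c in design_df.columns if c.startswith("infected:")
        }
        abundance = {
            c.split(":", 1)[1]: float(row[c]) for c in design_df.columns if c.startswith("abundance:")
        }
        designs.append(LibraryDesign(
            library_id=str(row["library_id"]), individual=str(row["individual"]),
            tissue=str(row["tissue"]), host_mapped_reads=int(row["host_mapped_reads"]),
            infection_status=infection, abundance_scale=abundance,
        ))
    genome = None
    if cfg.host_genome:
        genome = "".join(_io.read_fasta(cfg.host_genome).values())
    reads = _io.read_fasta(cfg.dna_reads) if cfg.dna_reads else {}
    return PipelineInputs(
        transcripts=_io.read_fasta(cfg.transcripts),
        reference_proteins=_io.read_fasta(cfg.protein_db),
        counts=counts, designs=designs, host_genome=genome, dna_reads=reads,
    )


def run_pipeline(config: PipelineConfig | str | Path) -> PipelineReport:
    """Run every stage and write per-stage outputs plus ``report.json``."""
    cfg = config if isinstance(config, PipelineConfig) else PipelineConfig.from_yaml(config)
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    if cfg.simulate:
        dataset = build_dataset(default_config(), seed=cfg.seed)
        dataset.write(outdir / "simulated")
        return run_on_dataset(dataset, cfg, outdir)
    return run_on_dataset(load_inputs(cfg), cfg, outdir)


def run_on_dataset(dataset, cfg: PipelineConfig, outdir: str | Path) -> PipelineReport:
    """Run the post-input stages on a :class:`Dataset` or :class:`PipelineInputs`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = PipelineReport(config_hash=cfg.digest(), seed=cfg.seed)
    timings = report.stage_timings

    def _stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            timings[name] = round(time.perf_counter() - t0, 3)
            report.stage_counts[name] = counts
            log.info("stage %-10s %s", name, counts)

        return done

    # -- search -------------------------------------------------------------
    done = _stage("search")
    hits = search(dataset.transcripts, dataset.reference_proteins, max_evalue=cfg.max_evalue)
    _io.write_hits_tsv(hits, outdir / "hits.tsv")
    candidates = collapse_hits(hits)
    done(transcripts=len(dataset.transcripts), hits=len(hits), candidates=len(candidates))

    # -- annotation + signals ----------------------------------------------
    done = _stage("annotate")
    orfs_by_seq = {}
    for cand in candidates:
        tid = cand.transcript_id
        seq = dataset.transcripts[tid]
        orfs = find_orfs(seq, min_aa=cfg.min_orf_aa)
        orfs_by_seq[tid] = orfs
        entry = {
            "best_hit": cand.best_hit.reference_id,
            "best_evalue": cand.best_hit.evalue,
            "orfs": [
                {"start": o.start, "end": o.end, "orientation": o.orientation,
                 "aa_length": o.aa_length, "mass_kda": o.mass_kda}
                for o in orfs
            ],
            "frameshift_sites": [],
        }
        if orfs:
            profile = utr_profile(seq, orfs)
            entry["utr5_len"] = profile.utr5_len
            entry["uuua_count"] = profile.uuua_count
            fwd = [o for o in orfs if o.orientation == "forward"]
            if fwd:
                for site in find_slippery_sites(seq, fwd[0]):
                    fused = fuse_frameshift_product(seq, fwd[0], site)
                    site.fused_protein_len = len(fused.protein)
                    entry["frameshift_sites"].append({
                        "position": site.position, "heptamer": site.heptamer,
                        "pattern_class": site.pattern_class,
                        "fused_protein_len": site.fused_protein_len,
                    })
        ph = panhandle_duplex(seq, seq, w=cfg.panhandle_window,
                              max_mismatch_run=cfg.panhandle_max_mismatch_run)
        entry["panhandle"] = {"duplex_len": ph.duplex_len, "paired_fraction": ph.paired_fraction}
        report.candidates[tid] = entry
    _io.write_orfs_gff3(orfs_by_seq, outdir / "orfs.gff3")
    done(candidates=len(candidates), orfs=sum(len(v) for v in orfs_by_seq.values()))

    # -- grouping -----------------------------------------------------------
    done = _stage("group")
    cand_ids = sorted(report.candidates)
    lengths = dataset.segment_lengths()
    host_reads = {d.library_id: d.host_mapped_reads for d in dataset.designs}
    counts_c = dataset.counts.loc[cand_ids]
    fpkm_c = fpkm_table(counts_c, lengths, pd.Series(host_reads))
    groups = group_segments(fpkm_c, counts_c, r_min=cfg.r_min,
                            fpkm_min=cfg.fpkm_min, frag_min=cfg.frag_min)
    groups_table(groups).to_csv(outdir / "groups.tsv", sep="\t", index=False)
    for g in groups:
        report.groups.append({
            "group_id": g.group_id, "members": g.members,
            "n_present_libraries": len(g.presence_pattern),
            "mean_r": g.mean_pairwise_r, "flag": g.flagged or "",
        })
        for tid in g.members:
            report.candidates[tid]["group_id"] = g.group_id
    done(groups=len(groups), multi=sum(1 for g in groups if len(g.members) > 1))

    # -- EVE screen ---------------------------------------------------------
    done = _stage("eve")
    n_eve = 0
    if dataset.host_genome:
        thresholds = EveThresholds(min_id=cfg.eve_min_id, min_len=cfg.eve_min_len,
                                   cov_min=cfg.eve_cov_min)
        scan_floor = cfg.eve_min_id - thresholds.ambiguous_margin
        for tid in cand_ids:
            seq = dataset.transcripts[tid]
            genome_hits = scan_integration(seq, dataset.host_genome, k=cfg.eve_k,
                                           min_id=scan_floor, min_len=cfg.eve_min_len)
            cov = dna_read_coverage(seq, dataset.dna_reads, k=cfg.eve_k) if dataset.dna_reads else 0.0
            evidence = IntegrationEvidence(candidate_id=tid, genome_hits=genome_hits,
                                           dna_covered_fraction=cov)
            verdict = classify_exogenous(evidence, thresholds)
            n_eve += verdict == "EVE"
            report.candidates[tid]["eve"] = {
                "verdict": verdict,
                "n_genome_hits": len(genome_hits),
                "dna_covered_fraction": cov,
            }
    done(candidates=len(cand_ids), eve=n_eve)

    # -- quantification -----------------------------------------------------
    done = _stage("quantify")
    fpkm_c.to_csv(outdir / "fpkm.tsv", sep="\t", index_label="transcript_id")
    n_viruses = 0
    if cand_ids:
        summary = summarize_profiles(dataset.counts, lengths, dataset.designs,
                                     viral_ids=set(cand_ids))
        summary.tissue_mean_fpkm.to_csv(outdir / "tissue_fpkm.tsv", sep="\t")
        n_viruses = len(summary.total_viral_fragments)
        for tid in cand_ids:
            report.candidates[tid]["fpkm"] = {
                lib: float(fpkm_c.loc[tid, lib]) for lib in fpkm_c.columns
            }
    done(viruses=n_viruses)

    (outdir / "report.json").write_text(report.to_json())
    return report
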