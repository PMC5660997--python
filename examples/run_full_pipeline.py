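"""Run the complete discovery pipeline and read the consolidated report.

simulate -> translated search -> collapse -> ORF annotation -> frameshift &
panhandle signals -> co-expression grouping -> EVE screen -> quantification.
Equivalent shell command: `aranevir run --seed 1 --outdir out/`.
"""

import tempfile
from pathlib import Path

from aranevir import PipelineConfig, run_pipeline

outdir = Path(tempfile.mkdtemp(prefix="aranevir_"))
report = run_pipeline(PipelineConfig(seed=1, outdir=str(outdir)))

print(f"stage counts: {report.stage_counts}\n")
n_eve = sum(c["eve"]["verdict"] == "EVE" for c in report.candidates.values())
multi = [g for g in report.groups if len(g["members"]) > 1]
fs = [(t, c["frameshift_sites"][0]) for t, c in report.candidates.items()
      if c["frameshift_sites"]]
print(f"{len(report.candidates)} candidates; {n_eve} flagged EVE; "
      f"{len(multi)} multipartite groups "
      f"({'/'.join(str(len(g['members'])) for g in multi)} segments)")
for tid, site in fs:
    print(f"frameshift on {tid}: {site['pattern_class']} at {site['position']}, "
          f"fused product {site['fused_protein_len']} aa")
print(f"\noutputs under {outdir}:")
for p in sorted(outdir.iterdir()):
    print(" ", p.name)
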