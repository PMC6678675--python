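"""Run the whole pipeline (reads -> report) on a generated fixture.

Equivalent to:  chiapet synth ... && chiapet run --config run.yaml
"""

import json
import tempfile
from pathlib import Path

from chiapet.pipeline import PipelineConfig, run_pipeline
from chiapet.synth import emit_fixture_suite

tmp = Path(tempfile.mkdtemp(prefix="chiapet_demo_"))
fdir = emit_fixture_suite(tmp, {"demo": {
    "n_molecules": 500, "seed": 5, "chrom_length": 200_000}})["demo"]
print(f"fixture written to {fdir}")

config = PipelineConfig(
    fastq1=str(fdir / "reads_1.fastq"), fastq2=str(fdir / "reads_2.fastq"),
    linker_file=str(fdir / "linkers.fa"), mode="short",
    genome_fasta=str(fdir / "genome.fa"),
    chrom_sizes=str(fdir / "genome.chrom.sizes"),
    output_dir=str(tmp), output_prefix="out", cutoff="8000",
)
workdir = run_pipeline(config)
counters = json.loads((workdir / "counters.json").read_text())
print("\nstage counters (the library-statistics ledger):")
for key in ("total_pets", "same_linker", "uniquely_mapped",
            "after_exact_merge", "after_similar_merge", "self_ligation",
            "inter_ligation", "other_short", "n_peaks", "n_interactions"):
    print(f"  {key}: {counters[key]}")
print(f"\nHTML report: {workdir / 'report' / 'report.html'}")
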