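"""End-to-end pipeline orchestration with mid-stream entry.

The seven steps (linker filtering, mapping, purification, categorization,
peak calling, interaction calling, report) each read their inputs from the
artifact files of the previous step, so a run may start at any step for
which the prerequisite artifacts exist, and stepwise execution equals one
monolithic run.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import categorize as cat
from . import interactions as ia
from . import peaks as pk
from . import purify as pu
from . import report as rp
from .io_core import (GenomeInfo, read_bed, read_bedpe, read_chrom_sizes,
                      read_fastq_pair, read_genome_fasta, read_linker_file,
                      write_bed, write_bedpe)
from .linkerfilter import LinkerFilterParams, TaggedPET, run_linker_filter
from .mapping import extract_unique_pets, map_tagged_pets

REQUIRED_SETTINGS = (
    "fastq1", "fastq2", "linker_file", "mode", "genome_fasta",
    "chrom_sizes", "output_dir", "output_prefix", "mapq_cutoff",
    "min_linker_score",
)

STEP_NAMES = {
    1: "filter", 2: "map", 3: "purify", 4: "categorize",
    5: "peaks", 6: "interactions", 7: "report",
}


@dataclass
class PipelineConfig:
    fastq1: str = ""
    fastq2: str = ""
    linker_file: str = ""
    mode: str = "short"
    genome_fasta: str = ""
    chrom_sizes: str = ""
    output_dir: str = "."
    output_prefix: str = "out"
    mapq_cutoff: int = 30
    min_linker_score: int = 14
    min_linker_diff: int = 2
    min_tag_len: int = 18
    max_tag_len: Optional[int] = 25
    cutoff: str = "auto"      # "auto" or integer bp
    extension: str = "auto"   # "auto" or integer bp
    peak_min_count: int = 3
    peak_pvalue: float = 1e-5
    min_pet: int = 3
    fdr: float = 0.05
    dedup_tolerance: int = 2
    anchors_bed: str = ""     # optional user anchors for interaction calling

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        missing = [k for k in REQUIRED_SETTINGS if k not in data]
        if missing:
            raise ValueError(f"missing required settings: {missing}")
        known = {k: v for k, v in data.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @property
    def workdir(self) -> Path:
        return Path(self.output_dir) / self.output_prefix


def _log(workdir: Path, step: int, **payload) -> None:
    with open(workdir / "pipeline.log.jsonl", "a") as fh:
        fh.write(json.dumps({"step": step, "name": STEP_NAMES[step], **payload},
                            sort_keys=True) + "\n")


def _counters_path(workdir: Path) -> Path:
    return workdir / "counters.json"


def _update_counters(workdir: Path, **values) -> dict:
    path = _counters_path(workdir)
    counters = json.loads(path.read_text()) if path.exists() else {}
    counters.update(values)
    path.write_text(json.dumps(counters, indent=1, sort_keys=True))
    return counters


def _require(path: Path, step: int) -> Path:
    if not path.exists():
        raise FileNotFoundError(
            f"step {step} ({STEP_NAMES[step]}) needs missing artifact: {path}")
    return path


def step_filter(config: PipelineConfig, workdir: Path) -> None:
    linkers = read_linker_file(config.linker_file, config.mode)
    params = LinkerFilterParams(
        min_score=config.min_linker_score, min_diff=config.min_linker_diff,
        min_tag_len=config.min_tag_len,
        max_tag_len=config.max_tag_len if config.mode == "short" else None,
    )
    pairs = read_fastq_pair(config.fastq1, config.fastq2)
    retained, stats = run_linker_filter(
        pairs, linkers, params,
        out_fastq1=workdir / "filtered_1.fastq",
        out_fastq2=workdir / "filtered_2.fastq",
        side_file=workdir / "filtered_side.tsv",
    )
    stats.save(workdir / "linker_stats.json")
    _update_counters(workdir, total_pets=stats.total, same_linker=stats.retained)
    _log(workdir, 1, total=stats.total, retained=stats.retained)


def step_map(config: PipelineConfig, workdir: Path) -> None:
    fq1 = _require(workdir / "filtered_1.fastq", 2)
    fq2 = _require(workdir / "filtered_2.fastq", 2)
    genome = read_genome_fasta(config.genome_fasta)
    tagged = [
        TaggedPET(pet_id=p.read_id, tag1=p.seq1, qual1=p.qual1, label1="A",
                  tag2=p.seq2, qual2=p.qual2, label2="A", pet_class="same")
        for p in read_fastq_pair(fq1, fq2)
    ]
    pets, counts = map_tagged_pets(tagged, genome)
    write_bedpe(pets, workdir / "mapped.bedpe")
    _update_counters(workdir, uniquely_mapped=counts["both_unique"])
    _log(workdir, 2, **counts)


def step_map_from_sam(config: PipelineConfig, workdir: Path, sam_path) -> None:
    """Mid-stream entry: reduce an externally produced SAM to mapped.bedpe."""
    pets, counts = extract_unique_pets(sam_path, config.mapq_cutoff)
    write_bedpe(pets, workdir / "mapped.bedpe")
    _update_counters(workdir, uniquely_mapped=counts["both_unique"])
    _log(workdir, 2, **counts)


def step_purify(config: PipelineConfig, workdir: Path) -> None:
    pets = list(read_bedpe(_require(workdir / "mapped.bedpe", 3)))
    exact, _ = pu.merge_exact(pets)
    similar, _ = pu.merge_similar(exact, tolerance=config.dedup_tolerance)
    write_bedpe(similar, workdir / "purified.bedpe")
    _update_counters(workdir, after_exact_merge=len(exact),
                     after_similar_merge=len(similar))
    _log(workdir, 3, exact=len(exact), similar=len(similar))


def step_categorize(config: PipelineConfig, workdir: Path) -> None:
    pets = list(read_bedpe(_require(workdir / "purified.bedpe", 4)))
    dists = cat.compute_span_distributions(pets)
    if config.cutoff == "auto":
        cutoff = cat.estimate_self_ligation_cutoff(dists)
    else:
        cutoff = int(config.cutoff)
    result = cat.categorize_pets(pets, cutoff)
    write_bedpe(result.self_ligation, workdir / "self_ligation.bedpe")
    write_bedpe(result.intra_inter, workdir / "intra_inter.bedpe")
    write_bedpe(result.inter_chrom, workdir / "inter_chrom.bedpe")
    write_bedpe(result.other, workdir / "other_short.bedpe")
    df = dists.to_frame()
    df.to_csv(workdir / "span_distributions.tsv", sep="\t", index=False)
    _update_counters(
        workdir, cutoff=cutoff, self_ligation=len(result.self_ligation),
        intra_inter_ligation=len(result.intra_inter),
        inter_chrom=len(result.inter_chrom),
        inter_ligation=len(result.intra_inter) + len(result.inter_chrom),
        other_short=len(result.other),
    )
    _log(workdir, 4, cutoff=cutoff, **result.counts)


def step_peaks(config: PipelineConfig, workdir: Path) -> None:
    pets = list(read_bedpe(_require(workdir / "self_ligation.bedpe", 5)))
    genome = read_chrom_sizes(config.chrom_sizes)
    peaks = pk.call_peaks(pets, genome, min_count=config.peak_min_count,
                          pvalue_cutoff=config.peak_pvalue)
    write_bed(pk.peaks_to_bed_rows(peaks), workdir / "peaks.bed")
    with open(workdir / "peaks.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\tpet_count\tlambda\tpvalue\n")
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.count}\t"
                     f"{p.lam:.6g}\t{p.pvalue:.6g}\n")
    _update_counters(workdir, n_peaks=len(peaks))
    _log(workdir, 5, n_peaks=len(peaks))


def step_interactions(config: PipelineConfig, workdir: Path) -> None:
    intra = list(read_bedpe(_require(workdir / "intra_inter.bedpe", 6)))
    inter = list(read_bedpe(_require(workdir / "inter_chrom.bedpe", 6)))
    genome = read_chrom_sizes(config.chrom_sizes)
    if config.extension == "auto":
        self_pets = list(read_bedpe(_require(workdir / "self_ligation.bedpe", 6)))
        ext = cat.median_self_ligation_span(self_pets) if self_pets else ia.DEFAULT_EXTENSION
    else:
        ext = int(config.extension)
    user_anchors = None
    if config.anchors_bed:
        user_anchors = [(c, s, e) for c, s, e, _, _ in read_bed(config.anchors_bed)]
    clusters, significant, diagnostics = ia.call_interactions(
        intra + inter, ext=ext, genome=genome, user_anchors=user_anchors,
        min_pet=config.min_pet, fdr=config.fdr)
    header = ("chromA\tstartA\tendA\tchromB\tstartB\tendB\t"
              "pet_count\tpvalue\tadjusted_p\tdistance\ttype\n")
    for name, rows in (("clusters.tsv", clusters), ("significant.tsv", significant)):
        with open(workdir / name, "w") as fh:
            fh.write("# BH family: clusters with >= 2 PETs; "
                     f"significant: adjusted p < {config.fdr} and "
                     f">= {config.min_pet} PETs\n")
            fh.write(header)
            for r in ia.clusters_to_rows(rows):
                fh.write("\t".join(str(v) for v in r.values()) + "\n")
    _update_counters(workdir, extension=ext, n_clusters=len(clusters),
                     n_interactions=len(significant), **diagnostics)
    _log(workdir, 6, extension=ext, clusters=len(clusters),
         significant=len(significant))


def step_report(config: PipelineConfig, workdir: Path) -> None:
    counters = json.loads(_require(_counters_path(workdir), 7).read_text())
    stage = rp.StageCounters(
        total_pets=counters["total_pets"],
        same_linker=counters["same_linker"],
        uniquely_mapped=counters["uniquely_mapped"],
        after_exact_merge=counters["after_exact_merge"],
        after_similar_merge=counters["after_similar_merge"],
        self_ligation=counters["self_ligation"],
        inter_ligation=counters["inter_ligation"],
        other_short=counters["other_short"],
        n_peaks=counters["n_peaks"],
        n_interactions=counters["n_interactions"],
        intra_inter_ligation=counters.get("intra_inter_ligation"),
    )
    lib_stats = rp.compute_library_stats(stage)

    clusters = _read_clusters(workdir / "clusters.tsv")
    cluster_stats = rp.compute_cluster_stats(clusters)

    plots = []
    span_path = workdir / "span_distributions.tsv"
    if span_path.exists():
        import pandas as pd

        df = pd.read_csv(span_path, sep="\t")
        dists = cat.SpanDistributions(
            bin_edges=__import__("numpy").append(df["bin_low"].to_numpy(),
                                                 df["bin_high"].iloc[-1]),
            counts={c: df[c].to_numpy() for c in cat.COMPOSITIONS},
            n={c: int(df[c].sum()) for c in cat.COMPOSITIONS},
        )
        plots.append(("Genomic span distributions by strand composition",
                      rp.span_distribution_plot(dists)))
    rp.render_report(lib_stats, cluster_stats, workdir / "report", plots=plots)
    _log(workdir, 7, report=str(workdir / "report" / "report.html"))


def _read_clusters(path):
    from .interactions import Anchor, InteractionCluster

    clusters = []
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "chromA")):
                continue
            f = line.rstrip("\n").split("\t")
            clusters.append(InteractionCluster(
                Anchor(f[0], int(f[1]), int(f[2])),
                Anchor(f[3], int(f[4]), int(f[5])),
                int(f[6]),
                float(f[7]) if f[7] else None,
                float(f[8]) if f[8] else None,
            ))
    return clusters


STEP_FUNCS = {
    1: step_filter, 2: step_map, 3: step_purify, 4: step_categorize,
    5: step_peaks, 6: step_interactions, 7: step_report,
}


def run_pipeline(config: PipelineConfig, start_step: int = 1,
                 stop_step: int = 7) -> Path:
    """Run steps ``start_step``..``stop_step``; returns the work directory."""
    if not (1 <= start_step <= stop_step <= 7):
        raise ValueError("steps must satisfy 1 <= start <= stop <= 7")
    workdir = config.workdir
    workdir.mkdir(parents=True, exist_ok=True)
    for step in range(start_step, stop_step + 1):
        STEP_FUNCS[step](config, workdir)
    return workdir
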