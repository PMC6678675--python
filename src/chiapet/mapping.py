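"""Alignment planning, the built-in exact toy mapper, and unique-PET extraction.

The external aligner (BWA) is an interface, not a dependency: ``plan_alignment``
emits the command lines the pipeline would run, and the pipeline accepts SAM or
BEDPE mid-stream so real alignments can be dropped in. The toy mapper performs
exact-occurrence search and is the default engine for synthetic data.
"""

from __future__ import annotations

import statistics
import subprocess
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pysam

from .io_core import GenomeInfo, MappedPET, read_sam_pairs

__all__ = [
    "MappingParams",
    "ToyAlignment",
    "plan_alignment",
    "toy_map",
    "map_tagged_pets",
    "extract_unique_pets",
    "reverse_complement",
]

_COMP = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class MappingParams:
    genome_index: str = ""
    mapq_cutoff: int = 30
    length_switch: int = 55  # bp: aln below, mem at/above (long mode)
    engine: str = "toy"  # toy | external-short | external-long

    def __post_init__(self):
        if self.mapq_cutoff < 0:
            raise ValueError("mapq_cutoff must be >= 0")


@dataclass(frozen=True)
class CommandPlan:
    engine: str
    subcommand: str  # "aln" or "mem"
    commands: tuple

    def text(self) -> str:
        return "\n".join(self.commands)


def _median_read_length(fastq_path) -> float:
    from .io_core import xopen

    lengths = []
    with xopen(fastq_path) as fh:
        for i, line in enumerate(fh):
            if i % 4 == 1:
                lengths.append(len(line.strip()))
    if not lengths:
        raise ValueError(f"{fastq_path}: no reads")
    return statistics.median(lengths)


def plan_alignment(fastq1, fastq2, params: MappingParams,
                   out_prefix: str = "mapped", dry_run: bool = True):
    """Build (and optionally run) the external alignment commands.

    Short-engine libraries use the short-read subcommand (aln + samse per
    mate); long-engine libraries pick aln vs mem per library by the median
    trimmed tag length against ``length_switch``.
    """
    if params.engine == "toy":
        raise ValueError("plan_alignment is for external engines; use map_tagged_pets")
    if not params.genome_index:
        raise FileNotFoundError("genome index path not set")
    if not dry_run and not Path(str(params.genome_index) + ".bwt").exists():
        raise FileNotFoundError(f"missing index: {params.genome_index}.bwt")
    if params.engine == "external-short":
        sub = "aln"
    else:
        med = min(_median_read_length(fastq1), _median_read_length(fastq2))
        sub = "aln" if med < params.length_switch else "mem"
    idx = params.genome_index
    cmds = []
    if sub == "aln":
        for i, fq in enumerate((fastq1, fastq2), 1):
            cmds.append(f"bwa aln {idx} {fq} > {out_prefix}_{i}.sai")
            cmds.append(f"bwa samse {idx} {out_prefix}_{i}.sai {fq} > {out_prefix}_{i}.sam")
    else:
        for i, fq in enumerate((fastq1, fastq2), 1):
            cmds.append(f"bwa mem {idx} {fq} > {out_prefix}_{i}.sam")
    plan = CommandPlan(params.engine, sub, tuple(cmds))
    if not dry_run:
        for cmd in plan.commands:
            subprocess.run(cmd, shell=True, check=True)
    return plan


# ---------------------------------------------------------------------------
# Toy mapper: exact unique-occurrence search, mapq 60.

MULTI = "multi"
UNMAPPED_TAG = "unmapped"


@dataclass(frozen=True)
class ToyAlignment:
    chrom: str
    start: int
    end: int
    strand: str
    mapq: int = 60


class ToyGenomeIndex:
    """Sorted-hash index of all k-mer start positions for exact lookup.

    Candidate positions come from a 2-bit-packed k-mer hash and are verified
    by direct string comparison, so hash collisions cannot create hits.
    """

    K = 16
    _CODE = np.zeros(128, dtype=np.uint64)
    _CODE[ord("C")] = 1
    _CODE[ord("G")] = 2
    _CODE[ord("T")] = 3

    def __init__(self, genome: dict):
        self.genome = genome
        self.chroms = list(genome)
        hashes, chrom_ids, positions = [], [], []
        for ci, chrom in enumerate(self.chroms):
            seq = genome[chrom]
            n = len(seq) - self.K + 1
            if n <= 0:
                continue
            codes = self._CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
            h = np.zeros(n, dtype=np.uint64)
            for j in range(self.K):
                h = (h << np.uint64(2)) | codes[j:j + n]
            hashes.append(h)
            chrom_ids.append(np.full(n, ci, dtype=np.int32))
            positions.append(np.arange(n, dtype=np.int64))
        h = np.concatenate(hashes)
        order = np.argsort(h, kind="stable")
        self._hashes = h[order]
        self._chrom_ids = np.concatenate(chrom_ids)[order]
        self._positions = np.concatenate(positions)[order]

    def _hash(self, query: str) -> int:
        h = 0
        for ch in query[:self.K]:
            h = (h << 2) | int(self._CODE[ord(ch)])
        return h

    def occurrences(self, query: str, limit: int = 2):
        """Up to ``limit`` exact occurrence positions of ``query``."""
        if len(query) < self.K:  # too short for the index; direct scan
            hits = []
            for chrom, seq in self.genome.items():
                pos = seq.find(query)
                while pos != -1:
                    hits.append((chrom, pos))
                    if len(hits) >= limit:
                        return hits
                    pos = seq.find(query, pos + 1)
            return hits
        h = np.uint64(self._hash(query))
        lo = int(np.searchsorted(self._hashes, h, side="left"))
        hi = int(np.searchsorted(self._hashes, h, side="right"))
        hits = []
        for i in range(lo, hi):
            chrom = self.chroms[self._chrom_ids[i]]
            pos = int(self._positions[i])
            if self.genome[chrom][pos:pos + len(query)] == query:
                hits.append((chrom, pos))
                if len(hits) >= limit:
                    break
        return hits


def toy_map(tag: str, genome):
    """Exact-match mapping: unique occurrence of the tag or its reverse
    complement -> ToyAlignment; zero hits -> "unmapped"; several -> "multi".

    ``genome`` may be a chrom->sequence dict or a prebuilt ToyGenomeIndex.
    """
    if not isinstance(genome, ToyGenomeIndex):
        genome = ToyGenomeIndex(genome)
    if not tag or "N" in tag:
        return UNMAPPED_TAG
    fwd = genome.occurrences(tag)
    if len(fwd) >= 2:
        return MULTI
    rc = reverse_complement(tag)
    rev = [] if rc == tag else genome.occurrences(rc)
    total = len(fwd) + len(rev)
    if total == 0:
        return UNMAPPED_TAG
    if total > 1:
        return MULTI
    if fwd:
        chrom, pos = fwd[0]
        return ToyAlignment(chrom, pos, pos + len(tag), "+")
    chrom, pos = rev[0]
    return ToyAlignment(chrom, pos, pos + len(tag), "-")


def map_tagged_pets(tagged_pets, genome):
    """Map TaggedPETs with the toy mapper.

    Returns (MappedPET list normalized+sorted, counts dict). A PET is kept
    only when both tags map uniquely.
    """
    index = genome if isinstance(genome, ToyGenomeIndex) else ToyGenomeIndex(genome)
    pets = []
    counts = {"total": 0, "both_unique": 0, "multi": 0, "unmapped": 0}
    for t in tagged_pets:
        counts["total"] += 1
        a1 = toy_map(t.tag1, index)
        a2 = toy_map(t.tag2, index)
        bad = [a for a in (a1, a2) if isinstance(a, str)]
        if bad:
            counts["multi" if MULTI in bad else "unmapped"] += 1
            continue
        counts["both_unique"] += 1
        pets.append(MappedPET(
            chrom1=a1.chrom, start1=a1.start, end1=a1.end, strand1=a1.strand,
            chrom2=a2.chrom, start2=a2.start, end2=a2.end, strand2=a2.strand,
            pet_id=t.pet_id, mapq1=a1.mapq, mapq2=a2.mapq,
        ).normalized())
    pets.sort(key=lambda p: p.sort_key())
    return pets, counts


def write_toy_sam(tagged_pets, genome: dict, genome_info: GenomeInfo, path) -> None:
    """Emit toy-mapper alignments as headerful SAM (mate flags set)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": c, "LN": genome_info[c]} for c in genome_info.chromosomes()],
    }
    refs = {c: i for i, c in enumerate(genome_info.chromosomes())}
    index = genome if isinstance(genome, ToyGenomeIndex) else ToyGenomeIndex(genome)
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for t in tagged_pets:
            for mate, tag, qual in ((1, t.tag1, t.qual1), (2, t.tag2, t.qual2)):
                aln = toy_map(tag, index)
                seg = pysam.AlignedSegment()
                seg.query_name = t.pet_id
                seg.flag = 0x1 | (0x40 if mate == 1 else 0x80)
                if isinstance(aln, str):
                    seg.flag |= 0x4
                    seg.query_sequence = tag or "N"
                    seg.query_qualities = pysam.qualitystring_to_array(qual or "!")
                    seg.reference_id = -1
                    seg.reference_start = -1
                    seg.mapping_quality = 0
                else:
                    if aln.strand == "-":
                        seg.flag |= 0x10
                        seg.query_sequence = reverse_complement(tag)
                        seg.query_qualities = pysam.qualitystring_to_array(qual[::-1])
                    else:
                        seg.query_sequence = tag
                        seg.query_qualities = pysam.qualitystring_to_array(qual)
                    seg.reference_id = refs[aln.chrom]
                    seg.reference_start = aln.start
                    seg.mapping_quality = aln.mapq
                    seg.cigarstring = f"{len(tag)}M"
                out.write(seg)


# ---------------------------------------------------------------------------

def extract_unique_pets(sam_path, mapq_cutoff: int = 30):
    """Reduce a SAM file to PETs whose both mates map with mapq >= cutoff.

    Returns (MappedPET list normalized+sorted, counts dict).
    """
    pets = []
    counts = {"total": 0, "both_unique": 0}
    for read_id, (a1, a2) in read_sam_pairs(sam_path):
        counts["total"] += 1
        if a1 is None or a2 is None:
            continue
        if a1.mapping_quality < mapq_cutoff or a2.mapping_quality < mapq_cutoff:
            continue
        counts["both_unique"] += 1
        pets.append(MappedPET(
            chrom1=a1.reference_name, start1=a1.reference_start,
            end1=a1.reference_end, strand1="-" if a1.is_reverse else "+",
            chrom2=a2.reference_name, start2=a2.reference_start,
            end2=a2.reference_end, strand2="-" if a2.is_reverse else "+",
            pet_id=read_id, mapq1=a1.mapping_quality, mapq2=a2.mapping_quality,
        ).normalized())
    pets.sort(key=lambda p: p.sort_key())
    return pets, counts
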