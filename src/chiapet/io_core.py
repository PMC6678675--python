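"""Readers, writers and shared record types for the pipeline.

All genomic intervals are 0-based half-open throughout the package (BED/BEDPE
native). The 5' position of a tag is its ``start`` on the plus strand and its
``end`` (exclusive bound) on the minus strand; every span, footprint and
extension computation uses this convention.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from typing import IO, Iterable, Iterator, Optional

import pysam
from Bio import SeqIO

__all__ = [
    "GenomeInfo",
    "RawPETPair",
    "MappedPET",
    "LinkerSet",
    "read_chrom_sizes",
    "read_fastq_pair",
    "write_fastq_pair",
    "read_sam_pairs",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "write_bed",
    "read_linker_file",
    "xopen",
]

_DNA = set("ACGTN")


def xopen(path, mode: str = "rt") -> IO:
    """Open *path*, transparently handling gzip by extension."""
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


@dataclass(frozen=True)
class GenomeInfo:
    """Ordered chromosome-name -> length map plus the total genome size."""

    lengths: dict

    def __post_init__(self):
        if not self.lengths:
            raise ValueError("GenomeInfo requires at least one chromosome")
        for name, length in self.lengths.items():
            if length <= 0:
                raise ValueError(f"chromosome {name!r} has non-positive length {length}")

    @property
    def total(self) -> int:
        return sum(self.lengths.values())

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.lengths

    def __getitem__(self, chrom: str) -> int:
        return self.lengths[chrom]

    def chromosomes(self):
        return list(self.lengths)


def read_chrom_sizes(path) -> GenomeInfo:
    """Read a 2-column chromosome-sizes TSV into a :class:`GenomeInfo`."""
    lengths: dict = {}
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            name = parts[0]
            if name in lengths:
                raise ValueError(f"{path}: duplicate chromosome {name!r}")
            lengths[name] = int(parts[1])
    return GenomeInfo(lengths)


def write_chrom_sizes(genome: GenomeInfo, path) -> None:
    with xopen(path, "wt") as fh:
        for name, length in genome.lengths.items():
            fh.write(f"{name}\t{length}\n")


@dataclass(frozen=True)
class RawPETPair:
    """One paired-end read before linker processing."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self):
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"{self.read_id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class MappedPET:
    """A purified paired-end tag: two genomic tags plus bookkeeping.

    Tags are canonically ordered so that tag1 <= tag2 by (chrom, start);
    :meth:`normalized` enforces the order. ``multiplicity`` counts the raw
    PETs collapsed into this record during purification.
    """

    chrom1: str
    start1: int
    end1: int
    strand1: str
    chrom2: str
    start2: int
    end2: int
    strand2: str
    pet_id: str = "."
    mapq1: int = 255
    mapq2: int = 255
    multiplicity: int = 1

    def __post_init__(self):
        for s, e in ((self.start1, self.end1), (self.start2, self.end2)):
            if not (0 <= s < e):
                raise ValueError(f"{self.pet_id}: invalid interval [{s}, {e})")
        if self.strand1 not in "+-" or self.strand2 not in "+-":
            raise ValueError(f"{self.pet_id}: strand must be + or -")

    def normalized(self) -> "MappedPET":
        if (self.chrom1, self.start1, self.end1) <= (self.chrom2, self.start2, self.end2):
            return self
        return replace(
            self,
            chrom1=self.chrom2, start1=self.start2, end1=self.end2,
            strand1=self.strand2, mapq1=self.mapq2,
            chrom2=self.chrom1, start2=self.start1, end2=self.end1,
            strand2=self.strand1, mapq2=self.mapq1,
        )

    @property
    def five_prime1(self) -> int:
        return self.start1 if self.strand1 == "+" else self.end1

    @property
    def five_prime2(self) -> int:
        return self.start2 if self.strand2 == "+" else self.end2

    @property
    def is_intra(self) -> bool:
        return self.chrom1 == self.chrom2

    @property
    def span(self) -> Optional[int]:
        """5'-to-5' distance between the two tags; None for inter-chromosomal."""
        if not self.is_intra:
            return None
        return abs(self.five_prime2 - self.five_prime1)

    def sort_key(self):
        return (self.chrom1, self.start1, self.end1, self.strand1,
                self.chrom2, self.start2, self.end2, self.strand2, self.pet_id)


@dataclass(frozen=True)
class LinkerSet:
    """Linker sequences for one library.

    Short mode carries the two half-linkers A and B with the barcode locus
    computed as the maximal run of positions where A and B differ. Long mode
    carries the bridge-linker plus strand and its reverse complement.
    """

    mode: str  # "short" | "long"
    linker_a: str = ""
    linker_b: str = ""
    bridge_f: str = ""
    bridge_r: str = ""
    barcode_offset: int = field(default=-1)
    barcode_length: int = field(default=0)

    def __post_init__(self):
        if self.mode not in ("short", "long"):
            raise ValueError(f"unknown linker mode {self.mode!r}")
        if self.mode == "short":
            if not self.linker_a or not self.linker_b:
                raise ValueError("short mode needs half-linkers A and B")
            if len(self.linker_a) != len(self.linker_b):
                raise ValueError("half-linkers A and B must have equal length")
            if self.barcode_offset < 0:
                off, length = _barcode_locus(self.linker_a, self.linker_b)
                object.__setattr__(self, "barcode_offset", off)
                object.__setattr__(self, "barcode_length", length)
        else:
            if not self.bridge_f or not self.bridge_r:
                raise ValueError("long mode needs bridge_f and bridge_r")

    @property
    def barcode_a(self) -> str:
        return self.linker_a[self.barcode_offset:self.barcode_offset + self.barcode_length]

    @property
    def barcode_b(self) -> str:
        return self.linker_b[self.barcode_offset:self.barcode_offset + self.barcode_length]


def _barcode_locus(a: str, b: str):
    diff = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
    if not diff:
        raise ValueError("half-linkers A and B are identical; no barcode")
    return diff[0], diff[-1] - diff[0] + 1


def read_linker_file(path, mode: str) -> LinkerSet:
    """Read a FASTA-like linker file.

    Records named ``A``/``B`` define the short-mode half-linkers; records
    named ``bridge_f``/``bridge_r`` define the long-mode bridge strands.
    """
    records = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    if mode == "short":
        if "A" not in records or "B" not in records:
            raise ValueError(f"{path}: short mode needs records named A and B")
        return LinkerSet(mode="short", linker_a=records["A"], linker_b=records["B"])
    if "bridge_f" not in records or "bridge_r" not in records:
        raise ValueError(f"{path}: long mode needs records bridge_f and bridge_r")
    return LinkerSet(mode="long", bridge_f=records["bridge_f"], bridge_r=records["bridge_r"])


# ---------------------------------------------------------------------------
# FASTQ

def _read_fastq_records(fh, path) -> Iterator[tuple]:
    lineno = 0
    while True:
        header = fh.readline()
        if not header:
            return
        lineno += 1
        if not header.startswith("@"):
            raise ValueError(f"{path}: line {lineno}: expected '@' header, got {header.strip()!r}")
        seq = fh.readline()
        plus = fh.readline()
        qual = fh.readline()
        if not qual:
            raise ValueError(f"{path}: line {lineno}: truncated record {header.strip()!r}")
        lineno += 3
        seq, qual = seq.strip(), qual.strip()
        if not plus.startswith("+"):
            raise ValueError(f"{path}: line {lineno - 1}: expected '+' separator")
        if len(seq) != len(qual):
            raise ValueError(f"{path}: line {lineno}: sequence/quality length mismatch")
        yield header[1:].strip().split()[0], seq.upper(), qual


def read_fastq_pair(path1, path2) -> Iterator[RawPETPair]:
    """Stream mate-paired FASTQ records as :class:`RawPETPair` objects."""
    with xopen(path1) as fh1, xopen(path2) as fh2:
        it1 = _read_fastq_records(fh1, path1)
        it2 = _read_fastq_records(fh2, path2)
        for rec1 in it1:
            try:
                rec2 = next(it2)
            except StopIteration:
                raise ValueError(f"{path2}: fewer records than {path1}") from None
            yield RawPETPair(rec1[0], rec1[1], rec1[2], rec2[1], rec2[2])
        if next(it2, None) is not None:
            raise ValueError(f"{path2}: more records than {path1}")


def write_fastq_pair(pairs: Iterable[RawPETPair], path1, path2) -> int:
    n = 0
    with xopen(path1, "wt") as fh1, xopen(path2, "wt") as fh2:
        for p in pairs:
            fh1.write(f"@{p.read_id}\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.read_id}\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# SAM

UNMAPPED = None  # sentinel for an unaligned mate


def read_sam_pairs(path):
    """Group primary SAM alignments by read id.

    Yields ``(read_id, (aln1, aln2))`` where each element is a pysam
    AlignedSegment or the ``UNMAPPED`` sentinel. PETs with an orphan mate
    (only one primary record present) are dropped and counted; the count is
    available on the generator's ``.orphans`` attribute after exhaustion via
    the returned helper object.
    """
    sam = pysam.AlignmentFile(str(path), "r", check_sq=False)
    if not sam.header.to_dict().get("SQ") and not sam.header.to_dict().get("HD"):
        raise ValueError(f"{path}: SAM file has no header")
    buckets: dict = {}
    for aln in sam:
        if aln.is_secondary or aln.is_supplementary:
            continue
        mate = 2 if aln.is_read2 else 1
        buckets.setdefault(aln.query_name, {})[mate] = aln
    sam.close()
    for read_id, mates in buckets.items():
        if 1 in mates and 2 in mates:
            a1, a2 = mates[1], mates[2]
            yield (
                read_id,
                (UNMAPPED if a1.is_unmapped else a1, UNMAPPED if a2.is_unmapped else a2),
            )


# ---------------------------------------------------------------------------
# BEDPE

def write_bedpe(pets: Iterable[MappedPET], path, genome: Optional[GenomeInfo] = None) -> int:
    """Write PETs as 10-column BEDPE; multiplicity rides in the score column."""
    n = 0
    with xopen(path, "wt") as fh:
        for pet in pets:
            if genome is not None:
                for chrom, end in ((pet.chrom1, pet.end1), (pet.chrom2, pet.end2)):
                    if chrom not in genome or end > genome[chrom]:
                        raise ValueError(
                            f"{pet.pet_id}: {chrom}:{end} outside genome bounds")
            fh.write(
                f"{pet.chrom1}\t{pet.start1}\t{pet.end1}\t"
                f"{pet.chrom2}\t{pet.start2}\t{pet.end2}\t"
                f"{pet.pet_id}\t{pet.multiplicity}\t{pet.strand1}\t{pet.strand2}\n"
            )
            n += 1
    return n


def read_bedpe(path) -> Iterator[MappedPET]:
    with xopen(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 10:
                raise ValueError(f"{path}: line {lineno}: expected 10 BEDPE columns")
            yield MappedPET(
                chrom1=f[0], start1=int(f[1]), end1=int(f[2]),
                chrom2=f[3], start2=int(f[4]), end2=int(f[5]),
                pet_id=f[6], multiplicity=int(f[7]),
                strand1=f[8], strand2=f[9],
            )


# ---------------------------------------------------------------------------
# BED

def write_bed(intervals, path) -> int:
    """Write (chrom, start, end[, name[, score]]) tuples as BED, sorted."""
    rows = []
    for iv in intervals:
        chrom, start, end = iv[0], int(iv[1]), int(iv[2])
        name = iv[3] if len(iv) > 3 else "."
        score = iv[4] if len(iv) > 4 else 0
        rows.append((chrom, start, end, name, score))
    rows.sort(key=lambda r: (r[0], r[1], r[2]))
    with xopen(path, "wt") as fh:
        for r in rows:
            fh.write(f"{r[0]}\t{r[1]}\t{r[2]}\t{r[3]}\t{r[4]}\n")
    return len(rows)


def read_bed(path):
    out = []
    with xopen(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else "."
            score: object = 0
            if len(f) > 4:
                try:
                    score = int(f[4])
                except ValueError:
                    try:
                        score = float(f[4])
                    except ValueError:
                        score = f[4]
            out.append((f[0], int(f[1]), int(f[2]), name, score))
    return out


def read_genome_fasta(path) -> dict:
    """Load a genome FASTA into a chrom -> uppercase-sequence dict."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
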