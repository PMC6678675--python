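"""Synthetic ChIA-PET libraries with full ground truth.

The generator emulates the construct geometry of proximity-ligation
sequencing so every pipeline stage can be exercised without any download:

* a random genome (optionally with planted two-copy repeats that defeat
  unique mapping);
* protein binding sites, where self-ligation fragments concentrate, and
  loops — site pairs joined by a fixed number of inter-ligation PETs;
* a PET population mixing self-ligation, intra-/inter-chromosomal
  inter-ligation and short-span "other" molecules at configurable fractions;
* linker classes (A_A/B_B same, A_B/B_A different, ambiguous), PCR
  duplicates (exact and ±2 bp similar copies) and optional base errors;
* short-read 36-bp "tag + half-linker" reads with TAAG/ATGT barcodes, or
  long-read constructs carrying a bridge linker on each usable mate.

Every emitted PET carries its truth record (source coordinates, category,
linker class, duplicate-of), so tests can reconcile any stage against the
ledger. Default fractions follow the quality profile of a deep RNAPII
library: ~91% same-linker PETs, ~31% PCR duplication, and a purified-PET
split of roughly 32% self-ligation / 40% inter-ligation / 27% other.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .io_core import GenomeInfo, LinkerSet, MappedPET, RawPETPair, write_fastq_pair
from .mapping import reverse_complement

__all__ = [
    "SynthConfig",
    "default_linkers",
    "generate_genome",
    "generate_molecules",
    "generate_mapped_pets",
    "generate_pet_library",
    "emit_fixture_suite",
]

# fabricated 16-mers carrying the 4-bp barcodes at offset 5
LINKER_A = "GTTGGTAAGGTCGGAC"
LINKER_B = "GTTGGATGTGTCGGAC"
BRIDGE_F = "ACGCGATATCTTATCTGAC"


def default_linkers(mode: str = "short") -> LinkerSet:
    if mode == "short":
        return LinkerSet(mode="short", linker_a=LINKER_A, linker_b=LINKER_B)
    return LinkerSet(mode="long", bridge_f=BRIDGE_F,
                     bridge_r=reverse_complement(BRIDGE_F))


@dataclass(frozen=True)
class SynthConfig:
    """Generator settings; the defaults are the package's reference library."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 500_000
    repeat_fraction: float = 0.0
    repeat_length: int = 200
    # library geometry
    mode: str = "short"
    read_len: int = 36
    tag_len: int = 20
    # distinct molecules and their category mix (purified-PET profile)
    n_molecules: int = 4000
    frac_self: float = 0.323
    frac_intra_inter: float = 0.217
    frac_inter_chrom: float = 0.186
    frac_other: float = 0.274
    # short-range span distribution (self-ligation and "other" molecules:
    # both are single-fragment-scale products, so they share it)
    self_span_kind: str = "lognormal"  # lognormal | loguniform
    self_span_median: float = 500.0
    self_span_sigma: float = 0.5
    self_span_low: float = 100.0
    self_span_high: float = 5000.0
    self_span_max: float = 7500.0  # truncation for the lognormal tail
    # inter-ligation distance distribution (log-uniform)
    inter_low: float = 12_000.0
    inter_high: Optional[float] = None  # default 0.8 * chrom_length
    # binding sites and loops
    n_sites: int = 20
    site_fraction: float = 0.8
    site_jitter: int = 150
    n_loops: int = 10
    pets_per_loop: int = 8
    min_loop_distance: int = 50_000
    # noise
    frac_aa: float = 0.437
    frac_bb: float = 0.4703
    frac_different: float = 0.0112
    frac_ambiguous: float = 0.0815
    duplication_rate: float = 0.31
    similar_dup_rate: float = 0.0026
    error_rate: float = 0.0
    multi_fraction: float = 0.0

    def __post_init__(self):
        cat = self.frac_self + self.frac_intra_inter + self.frac_inter_chrom + self.frac_other
        if abs(cat - 1.0) > 1e-9:
            raise ValueError(f"category fractions sum to {cat}, expected 1")
        mix = self.frac_aa + self.frac_bb + self.frac_different + self.frac_ambiguous
        if abs(mix - 1.0) > 1e-9:
            raise ValueError(f"linker-class fractions sum to {mix}, expected 1")
        for name in ("duplication_rate", "similar_dup_rate", "error_rate",
                     "multi_fraction", "site_fraction"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# Genome

BASES = np.frombuffer(b"ACGT", dtype="S1")


def generate_genome(config: SynthConfig, rng: Optional[np.random.Generator] = None):
    """Random genome with optional planted 2-copy repeats.

    Returns (genome dict, GenomeInfo, repeat truth list of
    (chrom, start, end, mirror_chrom, mirror_start)).
    """
    rng = config.rng() if rng is None else rng
    genome: Dict[str, str] = {}
    lengths: Dict[str, int] = {}
    for i in range(config.n_chroms):
        name = f"chr{i + 1}"
        arr = rng.choice(BASES, size=config.chrom_length)
        genome[name] = arr.tobytes().decode()
        lengths[name] = config.chrom_length
    info = GenomeInfo(lengths)
    repeats = []
    if config.repeat_fraction > 0:
        n_repeats = max(1, int(config.repeat_fraction * info.total
                               / (2 * config.repeat_length)))
        chroms = list(genome)
        for _ in range(n_repeats):
            c_src = chroms[rng.integers(len(chroms))]
            c_dst = chroms[rng.integers(len(chroms))]
            L = config.repeat_length
            s = int(rng.integers(0, lengths[c_src] - L))
            d = int(rng.integers(0, lengths[c_dst] - L))
            seg = genome[c_src][s:s + L]
            genome[c_dst] = genome[c_dst][:d] + seg + genome[c_dst][d + L:]
            repeats.append((c_src, s, s + L, c_dst, d))
    return genome, info, repeats


# ---------------------------------------------------------------------------
# Molecules

@dataclass(frozen=True)
class SimMolecule:
    """One distinct ligation product with its ground truth."""

    mol_id: int
    category: str  # self | intra_inter | inter_chrom | other
    chrom1: str
    start1: int
    end1: int
    strand1: str
    chrom2: str
    start2: int
    end2: int
    strand2: str
    site_id: int = -1
    loop_id: int = -1

    def to_mapped(self, pet_id: str, multiplicity: int = 1) -> MappedPET:
        return MappedPET(
            chrom1=self.chrom1, start1=self.start1, end1=self.end1,
            strand1=self.strand1, chrom2=self.chrom2, start2=self.start2,
            end2=self.end2, strand2=self.strand2, pet_id=pet_id,
            mapq1=60, mapq2=60, multiplicity=multiplicity,
        ).normalized()


def _tag_interval(five_prime: int, strand: str, length: int) -> Tuple[int, int]:
    """Interval of a tag whose 5' position (our convention) is ``five_prime``."""
    if strand == "+":
        return five_prime, five_prime + length
    return five_prime - length, five_prime


def _sample_self_span(config: SynthConfig, rng) -> int:
    if config.self_span_kind == "loguniform":
        lo, hi = math.log(config.self_span_low), math.log(config.self_span_high)
        return int(round(math.exp(rng.uniform(lo, hi))))
    mu = math.log(config.self_span_median)
    d = math.exp(rng.normal(mu, config.self_span_sigma))
    d = min(d, config.self_span_max)
    return max(int(round(d)), 2 * 2)


def site_positions(config: SynthConfig) -> List[Tuple[str, int]]:
    """Evenly spaced binding-site positions across the chromosome interiors."""
    per_chrom = max(1, config.n_sites // config.n_chroms)
    sites = []
    for i in range(config.n_chroms):
        chrom = f"chr{i + 1}"
        for j in range(per_chrom):
            pos = int((j + 1) * config.chrom_length / (per_chrom + 1))
            sites.append((chrom, pos))
    return sites


def plan_loops(config: SynthConfig, sites, rng) -> List[Tuple[int, int]]:
    """Pick ``n_loops`` site-index pairs on one chromosome, far enough apart."""
    loops = []
    by_chrom: Dict[str, List[int]] = {}
    for idx, (chrom, _) in enumerate(sites):
        by_chrom.setdefault(chrom, []).append(idx)
    chroms = sorted(by_chrom)
    attempts = 0
    while len(loops) < config.n_loops and attempts < 10_000:
        attempts += 1
        chrom = chroms[int(rng.integers(len(chroms)))]
        pool = by_chrom[chrom]
        a, b = rng.choice(pool, size=2, replace=False)
        a, b = int(min(a, b)), int(max(a, b))
        if abs(sites[a][1] - sites[b][1]) < config.min_loop_distance:
            continue
        if (a, b) in loops:
            continue
        loops.append((a, b))
    if len(loops) < config.n_loops:
        raise ValueError("could not place the requested loops; "
                         "increase chromosome length or site count")
    return loops


def generate_molecules(config: SynthConfig, rng: Optional[np.random.Generator] = None,
                       repeats=()):
    """Distinct molecules plus the site and loop plans.

    Returns (molecules, sites, loops). Loop PETs come on top of
    ``n_molecules`` and are intra-chromosomal inter-ligation by construction.
    """
    rng = config.rng() if rng is None else rng
    L = config.chrom_length
    tl = config.tag_len
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sites = site_positions(config)
    loops = plan_loops(config, sites, rng) if config.n_loops > 0 else []

    categories = rng.choice(
        ["self", "intra_inter", "inter_chrom", "other"],
        size=config.n_molecules,
        p=[config.frac_self, config.frac_intra_inter,
           config.frac_inter_chrom, config.frac_other],
    )
    inter_high = config.inter_high if config.inter_high is not None else 0.8 * L

    molecules: List[SimMolecule] = []
    mol_id = 0
    for cat in categories:
        chrom = chroms[int(rng.integers(len(chroms)))]
        site_id = -1
        if cat == "self":
            d = _sample_self_span(config, rng)
            if rng.random() < config.site_fraction:
                site_id = int(rng.integers(len(sites)))
                chrom, centre = sites[site_id]
                p1 = centre - d // 2 + int(rng.integers(-config.site_jitter,
                                                        config.site_jitter + 1))
            else:
                p1 = int(rng.integers(tl, L - d - tl))
            p1 = min(max(p1, tl), L - d - tl)
            s1, e1 = _tag_interval(p1, "-", tl)
            s2, e2 = _tag_interval(p1 + d, "+", tl)
            mol = SimMolecule(mol_id, "self", chrom, s1, e1, "-",
                              chrom, s2, e2, "+", site_id=site_id)
        elif cat == "other":
            comp = ("++", "+-", "--")[int(rng.integers(3))]
            # tags must stay ordered after normalization, hence d > tag length
            d = max(_sample_self_span(config, rng), tl + 1)
            p1 = int(rng.integers(tl + d, L - d - tl))
            s1, e1 = _tag_interval(p1, comp[0], tl)
            s2, e2 = _tag_interval(p1 + d, comp[1], tl)
            mol = SimMolecule(mol_id, "other", chrom, s1, e1, comp[0],
                              chrom, s2, e2, comp[1])
        elif cat == "intra_inter":
            comp = ("++", "+-", "-+", "--")[int(rng.integers(4))]
            d = int(round(math.exp(rng.uniform(math.log(config.inter_low),
                                               math.log(inter_high)))))
            d = min(d, L - 4 * tl)
            p1 = int(rng.integers(tl, L - d - tl))
            s1, e1 = _tag_interval(p1, comp[0], tl)
            s2, e2 = _tag_interval(p1 + d, comp[1], tl)
            mol = SimMolecule(mol_id, "intra_inter", chrom, s1, e1, comp[0],
                              chrom, s2, e2, comp[1])
        else:  # inter_chrom
            c1, c2 = rng.choice(len(chroms), size=2, replace=False)
            st1, st2 = ("+", "-")[int(rng.integers(2))], ("+", "-")[int(rng.integers(2))]
            p1 = int(rng.integers(tl, L - tl))
            p2 = int(rng.integers(tl, L - tl))
            s1, e1 = _tag_interval(p1, st1, tl)
            s2, e2 = _tag_interval(p2, st2, tl)
            mol = SimMolecule(mol_id, "inter_chrom", chroms[c1], s1, e1, st1,
                              chroms[c2], s2, e2, st2)
        molecules.append(mol)
        mol_id += 1

    for loop_id, (ia, ib) in enumerate(loops):
        (chrom, pos_a), (_, pos_b) = sites[ia], sites[ib]
        for _ in range(config.pets_per_loop):
            st1 = ("+", "-")[int(rng.integers(2))]
            st2 = ("+", "-")[int(rng.integers(2))]
            p1 = pos_a + int(rng.integers(-config.site_jitter, config.site_jitter + 1))
            p2 = pos_b + int(rng.integers(-config.site_jitter, config.site_jitter + 1))
            s1, e1 = _tag_interval(p1, st1, tl)
            s2, e2 = _tag_interval(p2, st2, tl)
            molecules.append(SimMolecule(mol_id, "intra_inter", chrom, s1, e1, st1,
                                         chrom, s2, e2, st2, loop_id=loop_id))
            mol_id += 1

    if config.multi_fraction > 0 and repeats:
        n_multi = int(round(config.multi_fraction * len(molecules)))
        idx = rng.choice(len(molecules), size=n_multi, replace=False)
        for i in idx:
            m = molecules[i]
            c_src, rs, re_, _, _ = repeats[int(rng.integers(len(repeats)))]
            start = int(rng.integers(rs, re_ - tl))
            molecules[i] = replace(m, chrom1=c_src, start1=start,
                                   end1=start + tl, strand1="+", site_id=-2)
    return molecules, sites, loops


@dataclass(frozen=True)
class EmittedPET:
    """One sequenced PET: a molecule plus duplication/linker-class truth."""

    pet_id: str
    molecule: SimMolecule
    linker_class: str  # A_A | B_B | A_B | ambiguous
    dup_type: str      # none | exact | similar
    shift1: int = 0
    shift2: int = 0


def _emit_duplicates(molecules, config: SynthConfig, rng):
    """Expand distinct molecules into the emitted PET stream (shuffled).

    The linker class is a property of the ligation construct, so duplicates
    inherit the class of their template molecule.
    """
    n = len(molecules)
    r = config.duplication_rate
    n_emitted = int(round(n / (1.0 - r)))
    n_exact = n_emitted - n
    n_similar = int(round(n_emitted * config.similar_dup_rate))
    mol_class = rng.choice(
        ["A_A", "B_B", "A_B", "ambiguous"],
        size=n,
        p=[config.frac_aa, config.frac_bb, config.frac_different, config.frac_ambiguous],
    )
    emitted = [(m, "none", 0, 0) for m in molecules]
    for i in rng.choice(n, size=n_exact, replace=True):
        emitted.append((molecules[int(i)], "exact", 0, 0))
    shifts = [-2, -1, 1, 2]
    for i in rng.choice(n, size=n_similar, replace=True):
        s1 = shifts[int(rng.integers(4))]
        s2 = shifts[int(rng.integers(4))]
        emitted.append((molecules[int(i)], "similar", s1, s2))
    order = rng.permutation(len(emitted))
    out = []
    for rank, j in enumerate(order):
        m, dup, s1, s2 = emitted[int(j)]
        out.append(EmittedPET(f"pet{rank:07d}", m, str(mol_class[m.mol_id]),
                              dup, s1, s2))
    return out


def _shifted(m: SimMolecule, s1: int, s2: int) -> SimMolecule:
    return replace(m, start1=m.start1 + s1, end1=m.end1 + s1,
                   start2=m.start2 + s2, end2=m.end2 + s2)


def _truth_frame(emitted) -> pd.DataFrame:
    rows = []
    for e in emitted:
        m = _shifted(e.molecule, e.shift1, e.shift2)
        rows.append({
            "pet_id": e.pet_id, "mol_id": e.molecule.mol_id,
            "category": e.molecule.category,
            "linker_class": e.linker_class, "dup_type": e.dup_type,
            "chrom1": m.chrom1, "start1": m.start1, "end1": m.end1,
            "strand1": m.strand1, "chrom2": m.chrom2, "start2": m.start2,
            "end2": m.end2, "strand2": m.strand2,
            "site_id": e.molecule.site_id, "loop_id": e.molecule.loop_id,
        })
    return pd.DataFrame(rows)


def generate_mapped_pets(config: SynthConfig):
    """Coordinate-level library: emitted MappedPETs (same-linker classes only)
    plus the truth ledger for all emitted PETs.

    Bypasses sequencing and mapping; the returned PETs are what a perfect
    mapper would recover from the same-linker subset.
    """
    rng = config.rng()
    _, info, repeats = generate_genome(config, rng) if config.repeat_fraction > 0 \
        else (None, GenomeInfo({f"chr{i + 1}": config.chrom_length
                                for i in range(config.n_chroms)}), [])
    molecules, sites, loops = generate_molecules(config, rng, repeats)
    emitted = _emit_duplicates(molecules, config, rng)
    truth = _truth_frame(emitted)
    pets = [
        _shifted(e.molecule, e.shift1, e.shift2).to_mapped(e.pet_id)
        for e in emitted if e.linker_class in ("A_A", "B_B")
    ]
    return pets, truth, {"genome_info": info, "sites": sites, "loops": loops}


# ---------------------------------------------------------------------------
# Read construction

def _tag_sequence(genome, chrom, start, end, strand) -> str:
    seq = genome[chrom][start:end]
    return seq if strand == "+" else reverse_complement(seq)


def _corrupt_barcode(linker: str, linkers: LinkerSet) -> str:
    pos = linkers.barcode_offset
    base = "G" if linker[pos] != "G" else "C"
    return linker[:pos] + base + linker[pos + 1:]


def _apply_errors(seq: str, rate: float, rng) -> str:
    if rate <= 0:
        return seq
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = "ACGT"[int(rng.integers(4))]
    return "".join(out)


def _short_reads(e: EmittedPET, genome, linkers: LinkerSet, config, rng):
    m = _shifted(e.molecule, e.shift1, e.shift2)
    tag1 = _tag_sequence(genome, m.chrom1, m.start1, m.end1, m.strand1)
    tag2 = _tag_sequence(genome, m.chrom2, m.start2, m.end2, m.strand2)
    if e.linker_class == "A_A":
        l1 = l2 = linkers.linker_a
    elif e.linker_class == "B_B":
        l1 = l2 = linkers.linker_b
    elif e.linker_class == "A_B":
        l1, l2 = linkers.linker_a, linkers.linker_b
    else:  # ambiguous: one corrupted barcode fails the exact-match criterion
        l1 = _corrupt_barcode(linkers.linker_a, linkers)
        l2 = linkers.linker_a
    seq1 = (tag1 + l1)[:config.read_len].ljust(config.read_len, "A")
    seq2 = (tag2 + l2)[:config.read_len].ljust(config.read_len, "A")
    seq1 = _apply_errors(seq1, config.error_rate, rng)
    seq2 = _apply_errors(seq2, config.error_rate, rng)
    q = "I" * config.read_len
    return RawPETPair(e.pet_id, seq1, q, seq2, q)


LONG_RETAINED = ("A_B", "B_A", "A_X", "X_A", "B_X", "X_B")


def _long_reads(e: EmittedPET, genome, linkers: LinkerSet, config, rng):
    """Long-mode construct: variable tag + bridge strand + partner filler."""
    m = _shifted(e.molecule, e.shift1, e.shift2)
    # map short-mode class truth onto long-mode combos: same-linker molecules
    # become proper +/− bridge PETs, different-linker become chimeric (both
    # plus-strand), ambiguous become linkerless
    combo = ("A_B" if e.linker_class == "A_A" else
             "B_A" if e.linker_class == "B_B" else
             "A_A" if e.linker_class == "A_B" else "X_X")
    labels = combo.split("_")
    bridge = {"A": linkers.bridge_f, "B": linkers.bridge_r, "X": ""}
    reads = []
    for tag_spec, label in (((m.chrom1, m.start1, m.end1, m.strand1), labels[0]),
                            ((m.chrom2, m.start2, m.end2, m.strand2), labels[1])):
        tag = _tag_sequence(genome, *tag_spec)
        seq = tag + bridge[label]
        filler = config.read_len - len(seq)
        if filler > 0:
            seq += "".join("ACGT"[int(rng.integers(4))] for _ in range(filler))
        seq = seq[:config.read_len]
        reads.append(_apply_errors(seq, config.error_rate, rng))
    q = "I" * config.read_len
    return RawPETPair(e.pet_id, reads[0], q, reads[1], q)


def generate_pet_library(config: SynthConfig, genome: Optional[dict] = None,
                         linkers: Optional[LinkerSet] = None):
    """Full read-level library.

    Returns (RawPETPair list, truth DataFrame, context dict with the genome,
    GenomeInfo, linkers, sites and loops). Deterministic per seed.
    """
    rng = config.rng()
    if genome is None:
        genome, info, repeats = generate_genome(config, rng)
    else:
        info = GenomeInfo({c: len(s) for c, s in genome.items()})
        repeats = []
    linkers = linkers or default_linkers(config.mode)
    molecules, sites, loops = generate_molecules(config, rng, repeats)
    emitted = _emit_duplicates(molecules, config, rng)
    truth = _truth_frame(emitted)
    builder = _short_reads if config.mode == "short" else _long_reads
    pairs = [builder(e, genome, linkers, config, rng) for e in emitted]
    context = {"genome": genome, "genome_info": info, "linkers": linkers,
               "sites": sites, "loops": loops, "repeats": repeats}
    return pairs, truth, context


def write_linker_fasta(linkers: LinkerSet, path) -> None:
    with open(path, "w") as fh:
        if linkers.mode == "short":
            fh.write(f">A\n{linkers.linker_a}\n>B\n{linkers.linker_b}\n")
        else:
            fh.write(f">bridge_f\n{linkers.bridge_f}\n>bridge_r\n{linkers.bridge_r}\n")


def write_genome_fasta(genome: dict, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in genome.items():
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


FIXTURES = {
    "tiny": {"n_molecules": 700, "seed": 11},
    "standard": {"n_molecules": 5600, "seed": 12},
}


def emit_fixture_suite(out_dir, sizes: Optional[dict] = None) -> dict:
    """Write the canonical fixture libraries (FASTQ + genome + truth ledger).

    Each fixture regenerates byte-identically from its pinned seed. Returns
    {name: fixture directory}.
    """
    from .io_core import write_chrom_sizes

    out_dir = Path(out_dir)
    written = {}
    for name, override in (sizes or FIXTURES).items():
        config = SynthConfig(**override)
        fdir = out_dir / name
        fdir.mkdir(parents=True, exist_ok=True)
        pairs, truth, ctx = generate_pet_library(config)
        write_genome_fasta(ctx["genome"], fdir / "genome.fa")
        write_chrom_sizes(ctx["genome_info"], fdir / "genome.chrom.sizes")
        write_linker_fasta(ctx["linkers"], fdir / "linkers.fa")
        write_fastq_pair(pairs, fdir / "reads_1.fastq", fdir / "reads_2.fastq")
        truth.to_csv(fdir / "truth.tsv", sep="\t", index=False)
        (fdir / "config.json").write_text(json.dumps(asdict(config), indent=1))
        written[name] = fdir
    return written
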