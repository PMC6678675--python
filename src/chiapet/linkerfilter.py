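"""Linker detection, PET classification and tag trimming.

Short-read libraries embed a half-linker (A or B, distinguished by a 4-bp
barcode) at the 3' end of each 36-bp read; long-read libraries embed a bridge
linker whose plus strand should appear on one mate and minus strand on the
other. A local alignment of each candidate linker against each read locates
the linker; the read prefix upstream of the linker start is the genomic tag.

A PET is classified from its two per-read linker labels:

* short mode — ``same`` (A_A or B_B, kept for mapping), ``different``
  (A_B/B_A, chimeric ligation, written to a side file), ``ambiguous``
  (any of the four acceptance criteria failed on either read);
* long mode — retained combinations AB, BA, AX, XA, BX, XB (X = no linker
  found) are usable; AA/BB are chimeric-excluded and XX ambiguous.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .io_core import LinkerSet, RawPETPair, write_fastq_pair, xopen

__all__ = [
    "LinkerAlignment",
    "TaggedPET",
    "LinkerFilterStats",
    "LinkerFilterParams",
    "align_linker",
    "classify_short_pet",
    "classify_long_pet",
    "run_linker_filter",
]

MATCH, MISMATCH, GAP = 1, -1, -2


@dataclass(frozen=True)
class LinkerAlignment:
    """Best local alignment of one linker against one read."""

    linker_id: str
    score: int
    read_start: int
    read_end: int
    linker_start: int
    linker_end: int
    # aligned column pairs (read_pos, linker_pos), gaps excluded
    pairs: tuple = ()

    def barcode_matched(self, read: str, linker: str, offset: int, length: int) -> bool:
        """True iff every barcode position of the linker aligned to an
        identical read base (exact 4-bp barcode match, criterion 4)."""
        wanted = set(range(offset, offset + length))
        seen = {}
        for rp, lp in self.pairs:
            if lp in wanted:
                seen[lp] = read[rp] == linker[lp]
        return len(seen) == length and all(seen.values())


def align_linker(read: str, linker: str, linker_id: str = "?") -> LinkerAlignment:
    """Smith–Waterman local alignment (match +1, mismatch −1, gap −2).

    Deterministic tie-break: among maximal-scoring cells the one with the
    smallest read end, then smallest linker end, is chosen, and the traceback
    prefers diagonal over gap moves; this yields the smallest read start among
    equivalent placements.
    """
    n, m = len(read), len(linker)
    if n == 0 or m == 0:
        raise ValueError("empty sequence")
    # H[i][j] = best score of alignment ending at read[i-1], linker[j-1]
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, bi, bj = 0, 0, 0
    for i in range(1, n + 1):
        ri = read[i - 1]
        Hi, Hi1 = H[i], H[i - 1]
        for j in range(1, m + 1):
            s = MATCH if (ri == linker[j - 1] and ri != "N") else MISMATCH
            v = Hi1[j - 1] + s
            up = Hi1[j] + GAP
            left = Hi[j - 1] + GAP
            cell = max(0, v, up, left)
            Hi[j] = cell
            if cell > best:
                best, bi, bj = cell, i, j
    if best == 0:
        return LinkerAlignment(linker_id, 0, 0, 0, 0, 0, ())
    # traceback, diagonal first
    i, j = bi, bj
    pairs = []
    while i > 0 and j > 0 and H[i][j] > 0:
        s = MATCH if (read[i - 1] == linker[j - 1] and read[i - 1] != "N") else MISMATCH
        if H[i][j] == H[i - 1][j - 1] + s:
            pairs.append((i - 1, j - 1))
            i, j = i - 1, j - 1
        elif H[i][j] == H[i - 1][j] + GAP:
            i -= 1
        else:
            j -= 1
    pairs.reverse()
    return LinkerAlignment(linker_id, best, i, bi, j, bj, tuple(pairs))


@dataclass(frozen=True)
class TaggedPET:
    """A PET after linker processing: trimmed tags plus classification."""

    pet_id: str
    tag1: str
    qual1: str
    label1: str  # A, B or X
    tag2: str
    qual2: str
    label2: str
    pet_class: str  # same | different | ambiguous | chimeric-excluded
    score1: int = 0
    score2: int = 0
    diff1: int = 0
    diff2: int = 0

    @property
    def combo(self) -> str:
        return f"{self.label1}_{self.label2}"


@dataclass
class LinkerFilterStats:
    """Running tallies for the linker-filtering report."""

    mode: str = "short"
    combo_counts: Counter = field(default_factory=Counter)
    class_counts: Counter = field(default_factory=Counter)
    best_score_hist: Counter = field(default_factory=Counter)
    score_diff_hist: Counter = field(default_factory=Counter)
    tag_length_hist: Counter = field(default_factory=Counter)
    total: int = 0
    retained: int = 0

    def to_dict(self) -> dict:
        return {
            "mode": self.mode,
            "total": self.total,
            "retained": self.retained,
            "combo_counts": dict(self.combo_counts),
            "class_counts": dict(self.class_counts),
            "best_score_hist": {str(k): v for k, v in sorted(self.best_score_hist.items())},
            "score_diff_hist": {str(k): v for k, v in sorted(self.score_diff_hist.items())},
            "tag_length_hist": {str(k): v for k, v in sorted(self.tag_length_hist.items())},
        }

    def save(self, path) -> None:
        with xopen(path, "wt") as fh:
            json.dump(self.to_dict(), fh, indent=1)


@dataclass(frozen=True)
class LinkerFilterParams:
    min_score: int = 14
    min_diff: int = 2
    min_tag_len: int = 18
    max_tag_len: Optional[int] = 25  # None = read length (long mode default)
    workers: int = 1

    def __post_init__(self):
        if self.workers < 1:
            raise ValueError("workers must be >= 1")


def _assign_short_read(read: str, linkers: LinkerSet, params: LinkerFilterParams):
    """Label one short-mode read A/B or fail; returns (label, tag_end, best, diff)."""
    aln_a = align_linker(read, linkers.linker_a, "A")
    aln_b = align_linker(read, linkers.linker_b, "B")
    # tie -> A before B
    best, second = (aln_a, aln_b) if aln_a.score >= aln_b.score else (aln_b, aln_a)
    diff = best.score - second.score
    if best.score < params.min_score:            # criterion (1)
        return None, 0, best.score, diff
    if diff < params.min_diff:                   # criterion (2)
        return None, 0, best.score, diff
    tag_len = best.read_start
    max_len = params.max_tag_len if params.max_tag_len is not None else len(read)
    if not (params.min_tag_len <= tag_len <= max_len):  # criterion (3)
        return None, 0, best.score, diff
    linker_seq = linkers.linker_a if best.linker_id == "A" else linkers.linker_b
    if not best.barcode_matched(read, linker_seq,
                                linkers.barcode_offset, linkers.barcode_length):
        return None, 0, best.score, diff         # criterion (4)
    return best.linker_id, best.read_start, best.score, diff


def classify_short_pet(pair: RawPETPair, linkers: LinkerSet,
                       params: LinkerFilterParams = LinkerFilterParams()) -> TaggedPET:
    """Classify a short-read PET as same / different / ambiguous.

    Each read independently passes the four criteria (alignment score,
    best-vs-second-best margin, tag-length range, exact barcode) to earn an
    A or B label; any failure on either read makes the PET ambiguous.
    """
    lab1, cut1, s1, d1 = _assign_short_read(pair.seq1, linkers, params)
    lab2, cut2, s2, d2 = _assign_short_read(pair.seq2, linkers, params)
    if lab1 is None or lab2 is None:
        cls = "ambiguous"
        lab1 = lab1 or "X"
        lab2 = lab2 or "X"
        cut1 = cut1 or len(pair.seq1)
        cut2 = cut2 or len(pair.seq2)
    elif lab1 == lab2:
        cls = "same"
    else:
        cls = "different"
    return TaggedPET(
        pet_id=pair.read_id,
        tag1=pair.seq1[:cut1], qual1=pair.qual1[:cut1], label1=lab1,
        tag2=pair.seq2[:cut2], qual2=pair.qual2[:cut2], label2=lab2,
        pet_class=cls, score1=s1, score2=s2, diff1=d1, diff2=d2,
    )


RETAINED_LONG = {"A_B", "B_A", "A_X", "X_A", "B_X", "X_B"}


def _assign_long_read(read: str, linkers: LinkerSet, min_score: int):
    aln_f = align_linker(read, linkers.bridge_f, "A")
    aln_r = align_linker(read, linkers.bridge_r, "B")
    best = aln_f if aln_f.score >= aln_r.score else aln_r
    if best.score < min_score:
        return "X", len(read), 0
    return best.linker_id, best.read_start, best.score


def classify_long_pet(pair: RawPETPair, linkers: LinkerSet,
                      params: LinkerFilterParams = LinkerFilterParams()) -> TaggedPET:
    """Classify a long-read PET by bridge-linker strand on each mate.

    Label A = bridge plus strand found, B = minus strand, X = neither above
    the score cutoff. AB/BA/AX/XA/BX/XB are usable; AA/BB indicate improper
    (chimeric) ligation; XX carries no linker evidence.
    """
    lab1, cut1, s1 = _assign_long_read(pair.seq1, linkers, params.min_score)
    lab2, cut2, s2 = _assign_long_read(pair.seq2, linkers, params.min_score)
    combo = f"{lab1}_{lab2}"
    if combo in RETAINED_LONG:
        cls = "same"
    elif combo == "X_X":
        cls = "ambiguous"
    else:
        cls = "chimeric-excluded"
    return TaggedPET(
        pet_id=pair.read_id,
        tag1=pair.seq1[:cut1], qual1=pair.qual1[:cut1], label1=lab1,
        tag2=pair.seq2[:cut2], qual2=pair.qual2[:cut2], label2=lab2,
        pet_class=cls, score1=s1, score2=s2,
    )


def classify_pet(pair: RawPETPair, linkers: LinkerSet,
                 params: LinkerFilterParams = LinkerFilterParams()) -> TaggedPET:
    if linkers.mode == "short":
        return classify_short_pet(pair, linkers, params)
    return classify_long_pet(pair, linkers, params)


def run_linker_filter(pairs: Iterable[RawPETPair], linkers: LinkerSet,
                      params: LinkerFilterParams = LinkerFilterParams(),
                      out_fastq1=None, out_fastq2=None,
                      side_file=None):
    """Filter a PET stream: returns (retained TaggedPETs, LinkerFilterStats).

    Retained PETs (same-linker in short mode; usable bridge combinations in
    long mode) with both tags at least ``min_tag_len`` long are written as a
    trimmed FASTQ pair when output paths are given. Non-retained classes go
    to ``side_file`` as TSV when given. The ``workers`` parameter is part of
    the interface contract (output is identical for any worker count).
    """
    stats = LinkerFilterStats(mode=linkers.mode)
    retained = []
    side = xopen(side_file, "wt") if side_file else None
    try:
        for pair in pairs:
            tagged = classify_pet(pair, linkers, params)
            stats.total += 1
            stats.combo_counts[tagged.combo] += 1
            stats.class_counts[tagged.pet_class] += 1
            stats.best_score_hist[tagged.score1] += 1
            stats.best_score_hist[tagged.score2] += 1
            stats.score_diff_hist[tagged.diff1] += 1
            stats.score_diff_hist[tagged.diff2] += 1
            keep = (
                tagged.pet_class == "same"
                and len(tagged.tag1) >= params.min_tag_len
                and len(tagged.tag2) >= params.min_tag_len
            )
            if keep:
                stats.retained += 1
                stats.tag_length_hist[len(tagged.tag1)] += 1
                stats.tag_length_hist[len(tagged.tag2)] += 1
                retained.append(tagged)
            elif side is not None:
                side.write(f"{tagged.pet_id}\t{tagged.pet_class}\t{tagged.combo}\t"
                           f"{tagged.tag1}\t{tagged.tag2}\n")
    finally:
        if side is not None:
            side.close()
    if out_fastq1 and out_fastq2:
        write_fastq_pair(
            (RawPETPair(t.pet_id, t.tag1, t.qual1, t.tag2, t.qual2) for t in retained),
            out_fastq1, out_fastq2,
        )
    return retained, stats
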