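"""Chromatin-interaction calling from inter-ligation PETs.

Each inter-ligation tag is extended 3'-ward from its 5' position to the
expected fragment length (default 500 bp, or the median self-ligation span in
auto mode, since a sequenced tag is only the visible end of its fragment).
Overlapping extended tags merge into anchors; each PET then joins an ordered
anchor pair, and the PETs sharing a pair form an interaction cluster. Cluster
significance uses a hypergeometric model — an urn of the N inter-ligation
PETs, nA of which touch anchor A; drawing the nB PETs at anchor B, the
observed overlap k is tested for enrichment:

    p = sum_{i=k}^{min(nA, nB)} C(nA, i) C(N-nA, nB-i) / C(N, nB)

followed by Benjamini–Hochberg adjustment over all clusters with k >= 2.
Users may supply their own anchor regions (e.g. ChIP-Seq peaks); tags outside
every region are then dropped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_core import GenomeInfo, MappedPET

__all__ = [
    "Anchor",
    "InteractionCluster",
    "extend_tags",
    "build_anchors",
    "hypergeometric_pvalue",
    "call_interactions",
    "DEFAULT_EXTENSION",
]

DEFAULT_EXTENSION = 500


@dataclass(frozen=True)
class Anchor:
    chrom: str
    start: int
    end: int
    n_tags: int = 0


@dataclass(frozen=True)
class InteractionCluster:
    anchor_a: Anchor
    anchor_b: Anchor
    count: int                      # supporting PETs (iab)
    pvalue: Optional[float] = None  # None for untested singletons
    adjusted_p: Optional[float] = None

    @property
    def is_intra(self) -> bool:
        return self.anchor_a.chrom == self.anchor_b.chrom

    @property
    def distance(self) -> Optional[int]:
        """Midpoint-to-midpoint genomic distance (intra-chromosomal only)."""
        if not self.is_intra:
            return None
        mid_a = (self.anchor_a.start + self.anchor_a.end) // 2
        mid_b = (self.anchor_b.start + self.anchor_b.end) // 2
        return abs(mid_b - mid_a)


def _extended_window(chrom: str, five_prime: int, strand: str, ext: int,
                     genome: Optional[GenomeInfo]) -> Tuple[int, int]:
    if strand == "+":
        lo, hi = five_prime, five_prime + ext
    else:
        lo, hi = five_prime - ext, five_prime
    lo = max(lo, 0)
    if genome is not None:
        hi = min(hi, genome[chrom])
    if hi <= lo:  # clipped to nothing at a chromosome edge
        lo, hi = max(lo - 1, 0), max(hi, 1)
    return lo, hi


def extend_tags(pets: Sequence[MappedPET], ext: int = DEFAULT_EXTENSION,
                genome: Optional[GenomeInfo] = None):
    """Extended-tag windows for each PET: list of ((chrom, lo, hi) tag1, tag2)."""
    if ext <= 0:
        raise ValueError("extension must be positive")
    out = []
    for pet in pets:
        p = pet.normalized()
        w1 = (p.chrom1, *_extended_window(p.chrom1, p.five_prime1, p.strand1, ext, genome))
        w2 = (p.chrom2, *_extended_window(p.chrom2, p.five_prime2, p.strand2, ext, genome))
        out.append((w1, w2))
    return out


def _merge_intervals(by_chrom: dict) -> List[Anchor]:
    anchors = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        lo, hi, n = ivs[0][0], ivs[0][1], 1
        for s, e in ivs[1:]:
            if s < hi:
                hi = max(hi, e)
                n += 1
            else:
                anchors.append(Anchor(chrom, lo, hi, n))
                lo, hi, n = s, e, 1
        anchors.append(Anchor(chrom, lo, hi, n))
    return anchors


def build_anchors(extended, user_anchors: Optional[Sequence[Tuple[str, int, int]]] = None):
    """Merge extended tags into anchors and assign each PET an anchor pair.

    Returns (anchors, assignments) where assignments[i] is (ai, bi) anchor
    indices for PET i, ``None`` when a tag falls outside every user anchor,
    or the string ``"self"`` when both tags land in one anchor.
    """
    if user_anchors is None:
        by_chrom: dict = {}
        for w1, w2 in extended:
            by_chrom.setdefault(w1[0], []).append((w1[1], w1[2]))
            by_chrom.setdefault(w2[0], []).append((w2[1], w2[2]))
        anchors = _merge_intervals(by_chrom)
    else:
        merged: dict = {}
        for chrom, s, e in user_anchors:
            merged.setdefault(chrom, []).append((s, e))
        anchors = _merge_intervals(merged)

    starts: dict = {}
    index: dict = {}
    for i, a in enumerate(anchors):
        starts.setdefault(a.chrom, []).append((a.start, a.end, i))
    for chrom in starts:
        starts[chrom].sort()
        index[chrom] = np.array([s for s, _, _ in starts[chrom]])

    def locate(chrom, lo, hi):
        if chrom not in index:
            return None
        pos = int(np.searchsorted(index[chrom], lo, side="right")) - 1
        # a tag may start before its anchor only in user-anchor mode
        for j in (pos, pos + 1):
            if 0 <= j < len(starts[chrom]):
                s, e, i = starts[chrom][j]
                if lo < e and hi > s:
                    return i
        return None

    assignments = []
    tag_counts = np.zeros(len(anchors), dtype=int)
    for w1, w2 in extended:
        i1 = locate(*w1)
        i2 = locate(*w2)
        if i1 is None or i2 is None:
            assignments.append(None)
            continue
        tag_counts[i1] += 1
        tag_counts[i2] += 1
        if i1 == i2:
            assignments.append("self")
        else:
            a, b = sorted((i1, i2), key=lambda i: (anchors[i].chrom, anchors[i].start))
            assignments.append((a, b))
    anchors = [Anchor(a.chrom, a.start, a.end, int(tag_counts[i]))
               for i, a in enumerate(anchors)]
    return anchors, assignments


def hypergeometric_pvalue(k: int, n_a: int, n_b: int, n_total: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k | N, nA, nB)."""
    if not (0 <= k <= min(n_a, n_b)) or n_a > n_total or n_b > n_total:
        raise ValueError(f"impossible configuration k={k} nA={n_a} nB={n_b} N={n_total}")
    if k == 0:
        return 1.0
    return float(min(1.0, stats.hypergeom.sf(k - 1, n_total, n_a, n_b)))


def call_interactions(inter_pets: Sequence[MappedPET],
                      ext: int = DEFAULT_EXTENSION,
                      genome: Optional[GenomeInfo] = None,
                      user_anchors: Optional[Sequence[Tuple[str, int, int]]] = None,
                      min_pet: int = 3,
                      fdr: float = 0.05):
    """Cluster inter-ligation PETs into anchor pairs and test enrichment.

    Returns (all clusters sorted by coordinates, significant clusters,
    diagnostics). Clusters with k >= 2 form the Benjamini–Hochberg family;
    significant = adjusted p < ``fdr`` and k >= ``min_pet``. Singletons are
    reported untested. ``diagnostics`` counts self-pair and dropped PETs.
    """
    extended = extend_tags(inter_pets, ext, genome)
    anchors, assignments = build_anchors(extended, user_anchors)

    pair_counts: dict = {}
    diagnostics = {"self_pairs": 0, "dropped": 0, "paired": 0}
    for assign in assignments:
        if assign is None:
            diagnostics["dropped"] += 1
        elif assign == "self":
            diagnostics["self_pairs"] += 1
        else:
            diagnostics["paired"] += 1
            pair_counts[assign] = pair_counts.get(assign, 0) + 1

    n_total = len(inter_pets) if user_anchors is None else (
        diagnostics["paired"] + diagnostics["self_pairs"])
    clusters = []
    tested = []
    for (ia, ib), k in pair_counts.items():
        a, b = anchors[ia], anchors[ib]
        cluster = InteractionCluster(a, b, k)
        if k >= 2:
            p = hypergeometric_pvalue(min(k, min(a.n_tags, b.n_tags)),
                                      a.n_tags, b.n_tags, max(n_total, max(a.n_tags, b.n_tags)))
            cluster = InteractionCluster(a, b, k, pvalue=p)
            tested.append(cluster)
        clusters.append(cluster)

    if tested:
        pvals = np.array([c.pvalue for c in tested])
        _, adjusted, _, _ = multipletests(pvals, method="fdr_bh")
        adj_map = {id(c): float(a) for c, a in zip(tested, adjusted)}
        clusters = [
            InteractionCluster(c.anchor_a, c.anchor_b, c.count, c.pvalue,
                               adj_map.get(id(c)))
            for c in clusters
        ]
    key = lambda c: (c.anchor_a.chrom, c.anchor_a.start, c.anchor_b.chrom, c.anchor_b.start)
    clusters.sort(key=key)
    significant = [c for c in clusters
                   if c.adjusted_p is not None and c.adjusted_p < fdr and c.count >= min_pet]
    return clusters, significant, diagnostics


def clusters_to_rows(clusters: Sequence[InteractionCluster]):
    """Flatten clusters into TSV-ready rows."""
    rows = []
    for c in clusters:
        rows.append({
            "chromA": c.anchor_a.chrom, "startA": c.anchor_a.start, "endA": c.anchor_a.end,
            "chromB": c.anchor_b.chrom, "startB": c.anchor_b.start, "endB": c.anchor_b.end,
            "pet_count": c.count,
            "pvalue": "" if c.pvalue is None else c.pvalue,
            "adjusted_p": "" if c.adjusted_p is None else c.adjusted_p,
            "distance": "" if c.distance is None else c.distance,
            "type": "intra" if c.is_intra else "inter",
        })
    return rows
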