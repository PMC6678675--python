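"""PCR-duplicate removal for mapped PETs.

Two passes: (1) collapse PETs mapped to exactly the same locations (likely
PCR amplification copies) into one record; (2) collapse *similar* PETs whose
two tags lie within a small tolerance (default ±2 bp) at both ends — these
typically stem from variable MmeI cutting length or trimming jitter, so
similarity is evaluated on the 5' tag positions, which the enzyme does not
move. Similar PETs are grouped transitively (single linkage); the group
representative is its highest-multiplicity member (ties: smallest
coordinates) and carries the summed multiplicity.
"""

from __future__ import annotations

from dataclasses import replace
from typing import List, Sequence, Tuple

from .io_core import MappedPET

__all__ = ["merge_exact", "merge_similar"]


def _exact_key(p: MappedPET):
    return (p.chrom1, p.start1, p.end1, p.strand1,
            p.chrom2, p.start2, p.end2, p.strand2)


def merge_exact(pets: Sequence[MappedPET]) -> Tuple[List[MappedPET], int]:
    """Collapse PETs with identical mapping locations (strand included).

    Returns (sorted unique PETs with summed multiplicities, merged count).
    """
    groups: dict = {}
    for pet in pets:
        pet = pet.normalized()
        key = _exact_key(pet)
        if key in groups:
            rep = groups[key]
            groups[key] = replace(rep, multiplicity=rep.multiplicity + pet.multiplicity)
        else:
            groups[key] = pet
    unique = sorted(groups.values(), key=lambda p: p.sort_key())
    return unique, len(pets) - len(unique)


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def merge_similar(pets: Sequence[MappedPET], tolerance: int = 2) -> Tuple[List[MappedPET], int]:
    """Single-linkage merge of PETs whose both 5' tag positions are within
    ``tolerance`` bp (same chromosomes and strands required).

    Expects exact-merge output; with tolerance 0 on exact-merged input this
    is the identity. Returns (sorted unique PETs, merged count).
    """
    if tolerance < 0:
        raise ValueError("tolerance must be >= 0")
    pets = [p.normalized() for p in pets]
    by_group: dict = {}
    for idx, p in enumerate(pets):
        by_group.setdefault((p.chrom1, p.strand1, p.chrom2, p.strand2), []).append(idx)

    dsu = _DSU(len(pets))
    for indices in by_group.values():
        indices.sort(key=lambda i: (pets[i].five_prime1, pets[i].five_prime2))
        # sliding window on fp1; pairwise check on fp2
        for a_pos, i in enumerate(indices):
            fp1_i = pets[i].five_prime1
            fp2_i = pets[i].five_prime2
            for j in indices[a_pos + 1:]:
                if pets[j].five_prime1 - fp1_i > tolerance:
                    break
                if abs(pets[j].five_prime2 - fp2_i) <= tolerance:
                    dsu.union(i, j)

    clusters: dict = {}
    for idx in range(len(pets)):
        clusters.setdefault(dsu.find(idx), []).append(idx)

    out = []
    for members in clusters.values():
        rep_idx = min(members,
                      key=lambda i: (-pets[i].multiplicity, pets[i].sort_key()))
        total = sum(pets[i].multiplicity for i in members)
        out.append(replace(pets[rep_idx], multiplicity=total))
    out.sort(key=lambda p: p.sort_key())
    return out, len(pets) - len(out)
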