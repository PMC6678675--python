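"""Poisson peak calling from self-ligation PETs.

Each self-ligation PET directly measures its DNA fragment, so its footprint —
the interval between the two tags' 5' positions — marks one protein-bound
fragment. Overlapping footprints merge into candidate regions; a region with
k footprints and length L is scored against a Poisson null with rate

    lambda = max(lambda_BG, lambda_5k, lambda_10k)

where lambda_BG = N (L + f) / G for N footprints of mean length f in a genome
of size G, and lambda_local rescales the footprint count in a 10-kb window
centred on the region (the max-of-lambdas guards against local background
inflation, as MACS does when no control library is available; the window
set is configurable). p = P(Poisson(lambda) >= k).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .io_core import GenomeInfo, MappedPET

__all__ = [
    "Peak",
    "self_pet_coverage_regions",
    "poisson_peak_pvalue",
    "call_peaks",
]

LOCAL_WINDOWS = (10_000,)


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    count: int
    lam: float
    pvalue: float

    @property
    def neg_log10_p(self) -> float:
        return float(-np.log10(max(self.pvalue, 1e-300)))


def _footprint(pet: MappedPET) -> Tuple[str, int, int]:
    p = pet.normalized()
    lo, hi = sorted((p.five_prime1, p.five_prime2))
    return (p.chrom1, lo, hi + 1)  # inclusive of both 5' bases


def self_pet_coverage_regions(self_pets: Sequence[MappedPET]):
    """Merge overlapping self-ligation footprints into candidate regions.

    Returns (regions, footprints) where regions are (chrom, start, end, k)
    sorted by coordinate and footprints the per-chromosome interval arrays
    reused for local-lambda computation.
    """
    by_chrom: dict = {}
    for pet in self_pets:
        chrom, lo, hi = _footprint(pet)
        by_chrom.setdefault(chrom, []).append((lo, hi))
    regions = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_lo, cur_hi, k = ivs[0][0], ivs[0][1], 1
        for lo, hi in ivs[1:]:
            if lo < cur_hi:  # strict overlap merges; touching intervals stay apart
                cur_hi = max(cur_hi, hi)
                k += 1
            else:
                regions.append((chrom, cur_lo, cur_hi, k))
                cur_lo, cur_hi, k = lo, hi, 1
        regions.append((chrom, cur_lo, cur_hi, k))
    return regions, {c: np.array(sorted(v)) for c, v in by_chrom.items()}


def poisson_peak_pvalue(k: int, region_length: int, n_pets: int,
                        mean_footprint: float, genome_size: int,
                        local_counts: Sequence[Tuple[int, int]] = ()) -> Tuple[float, float]:
    """Upper-tail Poisson p-value for k footprints in a region.

    ``local_counts`` holds (window size, footprint count in window) pairs;
    lambda is the max of the genome-wide and local rates. Returns (p, lambda).
    """
    if genome_size <= 0:
        raise ValueError("genome size must be positive")
    if k == 0:
        return 1.0, 0.0
    unit = region_length + mean_footprint
    lam = n_pets * unit / genome_size
    for window, count in local_counts:
        lam = max(lam, count * unit / window)
    p = float(stats.poisson.sf(k - 1, lam)) if lam > 0 else (0.0 if k > 0 else 1.0)
    return min(max(p, 0.0), 1.0), lam


def call_peaks(self_pets: Sequence[MappedPET], genome: GenomeInfo,
               min_count: int = 3, pvalue_cutoff: float = 1e-5,
               windows: Sequence[int] = LOCAL_WINDOWS) -> List[Peak]:
    """Call peaks from self-ligation PETs; returns sorted, disjoint peaks."""
    if not self_pets:
        return []
    regions, footprints = self_pet_coverage_regions(self_pets)
    n_pets = sum(len(v) for v in footprints.values())
    mean_fp = float(np.mean([hi - lo for v in footprints.values() for lo, hi in v]))
    peaks = []
    starts = {c: v[:, 0] for c, v in footprints.items()}
    ends = {c: np.sort(v[:, 1]) for c, v in footprints.items()}
    for chrom, start, end, k in regions:
        if k < min_count:
            continue
        centre = (start + end) // 2
        local = []
        for w in windows:
            lo, hi = centre - w // 2, centre + w // 2
            # footprints overlapping [lo, hi): start < hi and end > lo
            n_start_before_hi = int(np.searchsorted(starts[chrom], hi, side="left"))
            n_end_before_lo = int(np.searchsorted(ends[chrom], lo, side="right"))
            local.append((w, max(0, n_start_before_hi - n_end_before_lo)))
        p, lam = poisson_peak_pvalue(k, end - start, n_pets, mean_fp,
                                     genome.total, local)
        if p <= pvalue_cutoff:
            peaks.append(Peak(chrom, start, end, k, lam, p))
    return peaks


def peaks_to_bed_rows(peaks: Sequence[Peak]):
    return [(p.chrom, p.start, p.end, f"peak_{i + 1}", round(p.neg_log10_p, 3))
            for i, p in enumerate(peaks)]
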