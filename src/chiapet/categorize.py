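"""PET categorization: self-ligation vs inter-ligation, with a data-driven
span cutoff.

Self-ligation PETs — both tags from one fragment — have a fixed signature:
minus-strand tag upstream of plus-strand tag (the tags point outward from the
fragment ends as sequenced) on the same chromosome, with a short span. Genuine
inter-ligation PETs occur in all four strand compositions with (to a good
approximation) the same span distribution, so the excess of −/+ PETs over the
mean of the ++, +−, −− compositions at short spans isolates the self-ligation
signal; the span where that excess fades into noise is the cutoff separating
self-ligation from intra-chromosomal inter-ligation PETs (around 8 kb in
typical libraries; 8000 bp is the fallback default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from .io_core import MappedPET

__all__ = [
    "SpanDistributions",
    "CategoryResult",
    "compute_span_distributions",
    "estimate_self_ligation_cutoff",
    "categorize_pets",
    "DEFAULT_CUTOFF",
    "default_span_bins",
]

DEFAULT_CUTOFF = 8000
COMPOSITIONS = ("++", "+-", "-+", "--")


def default_span_bins(low: float = 100.0, high: float = 1e8,
                      per_decade: int = 25) -> np.ndarray:
    """Log-spaced histogram bin edges (default 25 bins per decade, 100 bp–100 Mb)."""
    n_decades = np.log10(high / low)
    n_bins = int(round(n_decades * per_decade))
    return np.logspace(np.log10(low), np.log10(high), n_bins + 1)


@dataclass
class SpanDistributions:
    """Per-strand-composition histograms of intra-chromosomal PET spans."""

    bin_edges: np.ndarray
    counts: dict  # composition -> np.ndarray of len(bin_edges) - 1
    n: dict      # composition -> int

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame({"bin_low": self.bin_edges[:-1], "bin_high": self.bin_edges[1:]})
        for comp in COMPOSITIONS:
            df[comp] = self.counts[comp]
        return df


def _composition(pet: MappedPET) -> str:
    """Strand composition read as (leftmost tag strand, rightmost tag strand)."""
    p = pet.normalized()
    return p.strand1 + p.strand2


def compute_span_distributions(pets: Sequence[MappedPET],
                               bins: Optional[np.ndarray] = None) -> SpanDistributions:
    """Histogram the 5'-to-5' spans of intra-chromosomal PETs per composition.

    Spans below the first edge are clipped into the first bin; spans above
    the last edge into the last bin.
    """
    edges = default_span_bins() if bins is None else np.asarray(bins, dtype=float)
    spans = {c: [] for c in COMPOSITIONS}
    for pet in pets:
        if not pet.is_intra:
            continue
        spans[_composition(pet)].append(pet.span)
    counts, n = {}, {}
    nb = len(edges) - 1
    for comp, values in spans.items():
        if values:
            arr = np.clip(np.asarray(values, dtype=float), edges[0], np.nextafter(edges[-1], 0))
            idx = np.clip(np.searchsorted(edges, arr, side="right") - 1, 0, nb - 1)
            counts[comp] = np.bincount(idx, minlength=nb)
        else:
            counts[comp] = np.zeros(nb, dtype=int)
        n[comp] = len(values)
    return SpanDistributions(edges, counts, n)


def estimate_self_ligation_cutoff(dists: SpanDistributions,
                                  noise_fraction: float = 0.05,
                                  fallback: int = DEFAULT_CUTOFF) -> int:
    """Estimate the self-ligation span cutoff from the −/+ excess curve.

    Per bin, excess = count(−/+) − mean(count(++), count(+−), count(−−)).
    Bins where the excess clears ``noise_fraction`` of the mean-other level
    (or where −/+ counts exist with no other-composition background) are
    "signal" bins; the cutoff is the upper edge of the last bin of the run
    carrying the most excess mass. Falls back to ``fallback`` (default
    8000 bp) when the distributions carry no usable signal.
    """
    mp = dists.counts["-+"].astype(float)
    others = np.vstack([dists.counts[c] for c in ("++", "+-", "--")]).astype(float)
    if mp.sum() == 0 or others.sum() == 0:
        import warnings

        warnings.warn("empty span distributions; using fallback cutoff", stacklevel=2)
        return int(fallback)
    mean_other = others.mean(axis=0)
    excess = mp - mean_other
    signal = (excess > noise_fraction * mean_other) & (mp > 0)
    if not signal.any():
        return int(fallback)
    # contiguous runs of signal bins; pick the one with the largest excess mass
    runs = []
    start = None
    for i, flag in enumerate(signal):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(signal) - 1))
    best = max(runs, key=lambda r: excess[r[0]:r[1] + 1].sum())
    if excess[best[0]:best[1] + 1].sum() < 5:  # indistinguishable from noise
        return int(fallback)
    return int(round(dists.bin_edges[best[1] + 1]))


@dataclass
class CategoryResult:
    """The four-way partition of purified PETs plus the cutoff used."""

    self_ligation: List[MappedPET] = field(default_factory=list)
    intra_inter: List[MappedPET] = field(default_factory=list)
    inter_chrom: List[MappedPET] = field(default_factory=list)
    other: List[MappedPET] = field(default_factory=list)
    cutoff: int = DEFAULT_CUTOFF

    @property
    def counts(self) -> dict:
        return {
            "self_ligation": len(self.self_ligation),
            "intra_inter": len(self.intra_inter),
            "inter_chrom": len(self.inter_chrom),
            "other": len(self.other),
        }

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def categorize_pets(pets: Sequence[MappedPET], cutoff: int = DEFAULT_CUTOFF) -> CategoryResult:
    """Partition purified PETs into the four categories.

    self-ligation: same chromosome, leftmost tag on −, rightmost on +, span
    <= cutoff. inter-chromosomal: different chromosomes. intra-chromosomal
    inter-ligation: same chromosome, span > cutoff (any composition). other:
    same chromosome, span <= cutoff, composition not (−, +).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    result = CategoryResult(cutoff=int(cutoff))
    for pet in pets:
        p = pet.normalized()
        if not p.is_intra:
            result.inter_chrom.append(p)
        elif p.span > cutoff:
            result.intra_inter.append(p)
        elif p.strand1 == "-" and p.strand2 == "+":
            result.self_ligation.append(p)
        else:
            result.other.append(p)
    return result


def median_self_ligation_span(self_pets: Sequence[MappedPET]) -> int:
    """Median 5'-to-5' span of self-ligation PETs (the auto tag-extension length)."""
    if not self_pets:
        raise ValueError("no self-ligation PETs")
    return int(round(float(np.median([p.span for p in self_pets]))))
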