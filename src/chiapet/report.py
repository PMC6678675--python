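"""Library-quality statistics, cluster tables and the HTML report.

The library ledger tracks ten ordered stage counts — total PETs (1),
same-linker PETs (2), uniquely mapped (3), after exact duplicate merge (4),
after similar merge (5), self-ligation (6), inter-ligation (7), other short
PETs (8), peak count (9), interaction count (10) — plus the derived quality
percentages, each at a declared numerator/denominator pairing. Percentages
are rounded half-up to two decimals with trailing zeros stripped, so a
recomputed table cell matches the printed report bit for bit.
"""

from __future__ import annotations

import base64
import io
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import List, Optional, Sequence

from .interactions import InteractionCluster

__all__ = [
    "StageCounters",
    "LibraryStats",
    "ClusterStats",
    "compute_library_stats",
    "compute_cluster_stats",
    "render_report",
    "format_percentage",
]


def format_percentage(numerator: float, denominator: float, decimals: int = 2) -> str:
    """100*num/den, rounded half-up to ``decimals``, trailing zeros stripped.

    Returns "N/A" for a zero denominator.
    """
    if denominator == 0:
        return "N/A"
    pct = Decimal(100) * Decimal(numerator) / Decimal(denominator)
    q = pct.quantize(Decimal(1).scaleb(-decimals), rounding=ROUND_HALF_UP)
    text = format(q.normalize(), "f")
    return text


def percentage_value(numerator: float, denominator: float,
                     decimals: int = 2) -> Optional[float]:
    s = format_percentage(numerator, denominator, decimals)
    return None if s == "N/A" else float(s)


@dataclass(frozen=True)
class StageCounters:
    """Raw stage counts collected while the pipeline runs."""

    total_pets: int
    same_linker: int
    uniquely_mapped: int
    after_exact_merge: int
    after_similar_merge: int
    self_ligation: int
    inter_ligation: int
    other_short: int
    n_peaks: int
    n_interactions: int
    intra_inter_ligation: Optional[int] = None  # intra-chromosomal subset of (7)


# (label, numerator stage, denominator stage) for every derived percentage
PERCENTAGE_PAIRINGS = (
    ("same_linker_over_total", "same_linker", "total_pets"),
    ("unique_over_same_linker", "uniquely_mapped", "same_linker"),
    ("unique_over_total", "uniquely_mapped", "total_pets"),
    ("exact_merge_over_unique", "after_exact_merge", "uniquely_mapped"),
    ("exact_merge_over_total", "after_exact_merge", "total_pets"),
    ("similar_over_exact", "after_similar_merge", "after_exact_merge"),
    ("similar_over_total", "after_similar_merge", "total_pets"),
    ("self_over_purified", "self_ligation", "after_similar_merge"),
    ("self_over_total", "self_ligation", "total_pets"),
    ("inter_over_purified", "inter_ligation", "after_similar_merge"),
    ("inter_over_total", "inter_ligation", "total_pets"),
    ("other_over_purified", "other_short", "after_similar_merge"),
    ("other_over_total", "other_short", "total_pets"),
    ("intra_inter_over_inter", "intra_inter_ligation", "inter_ligation"),
)


@dataclass
class LibraryStats:
    counters: StageCounters
    percentages: dict = field(default_factory=dict)  # label -> formatted string

    def validate(self) -> None:
        c = self.counters
        checks = [
            ("(6)+(7)+(8) == (5)",
             c.self_ligation + c.inter_ligation + c.other_short == c.after_similar_merge),
            ("(2) <= (1)", c.same_linker <= c.total_pets),
            ("(3) <= (2)", c.uniquely_mapped <= c.same_linker),
            ("(4) <= (3)", c.after_exact_merge <= c.uniquely_mapped),
            ("(5) <= (4)", c.after_similar_merge <= c.after_exact_merge),
        ]
        failed = [name for name, ok in checks if not ok]
        if failed:
            raise ValueError(f"library-statistics reconciliation failed: {failed}; "
                             f"counters={c}")

    def rows(self):
        c = self.counters
        return [
            ("Total PETs", c.total_pets, "(1)"),
            ("Same-linker PETs after linker filtering", c.same_linker, "(2)"),
            ("Uniquely mapped same-linker PETs", c.uniquely_mapped, "(3)"),
            ("Merging same same-linker PETs", c.after_exact_merge, "(4)"),
            ("Merging similar same-linker PETs", c.after_similar_merge, "(5)"),
            ("Self-ligation PETs", c.self_ligation, "(6)"),
            ("Inter-ligation PETs", c.inter_ligation, "(7)"),
            ("Other PETs with short distance", c.other_short, "(8)"),
            ("Peaks from self-ligation", c.n_peaks, "(9)"),
            ("Interacting pairs", c.n_interactions, "(10)"),
        ]

    def quality_rows(self):
        """The seven library-quality indicators."""
        p = self.percentages
        c = self.counters
        return [
            ("Percentage of same-linker PETs over total PETs",
             p["same_linker_over_total"]),
            ("Percentage of uniquely mappable PETs over total PETs",
             p["unique_over_total"]),
            ("Percentage of PETs after merging those mapped to the same "
             "positions exactly over uniquely mappable PETs",
             p["exact_merge_over_unique"]),
            ("Percentage of inter-ligation PETs over PETs after purification",
             p["inter_over_purified"]),
            ("Percentage of intra-chromosomal inter-ligation PETs over "
             "inter-ligation PETs", p.get("intra_inter_over_inter", "N/A")),
            ("Number of peaks", str(c.n_peaks)),
            ("Number of interactions", str(c.n_interactions)),
        ]


def compute_library_stats(counters: StageCounters) -> LibraryStats:
    """Derive every quality percentage from the stage counters and validate."""
    stats = LibraryStats(counters=counters)
    for label, num_name, den_name in PERCENTAGE_PAIRINGS:
        num = getattr(counters, num_name)
        if num is None:
            continue
        den = getattr(counters, den_name)
        stats.percentages[label] = format_percentage(num, den if den is not None else 0)
    stats.validate()
    return stats


# ---------------------------------------------------------------------------
# Cluster tables

PET_COUNT_BINS = tuple(range(2, 10)) + ("ge10",)
SPAN_BINS = ("lt100kb", "100kb_1Mb", "1Mb_10Mb", "gt10Mb", "inter")


def _pet_count_bin(k: int):
    return k if k < 10 else "ge10"


def _span_bin(cluster: InteractionCluster) -> str:
    if not cluster.is_intra:
        return "inter"
    d = cluster.distance
    if d < 100_000:
        return "lt100kb"
    if d < 1_000_000:  # left-closed right-open bins
        return "100kb_1Mb"
    if d < 10_000_000:
        return "1Mb_10Mb"
    return "gt10Mb"


@dataclass
class ClusterStats:
    by_pet_count: dict = field(default_factory=dict)  # bin -> {total, intra, inter}
    span_table: dict = field(default_factory=dict)    # span bin -> count

    @property
    def total(self) -> int:
        return sum(v["total"] for v in self.by_pet_count.values())

    @property
    def total_intra(self) -> int:
        return sum(v["intra"] for v in self.by_pet_count.values())

    @property
    def total_inter(self) -> int:
        return sum(v["inter"] for v in self.by_pet_count.values())

    def validate(self) -> None:
        for b, v in self.by_pet_count.items():
            if v["intra"] + v["inter"] != v["total"]:
                raise ValueError(f"cluster bin {b}: intra+inter != total")
        span_intra = sum(v for k, v in self.span_table.items() if k != "inter")
        if span_intra != self.total_intra:
            raise ValueError("span-table intra total does not reconcile")

    def rows(self):
        out = []
        for b in PET_COUNT_BINS:
            v = self.by_pet_count.get(b, {"total": 0, "intra": 0, "inter": 0})
            pct = format_percentage(v["intra"], v["total"]) if v["total"] else "N/A"
            out.append((b, v["total"], v["intra"], v["inter"], pct))
        out.append(("total", self.total, self.total_intra, self.total_inter,
                    format_percentage(self.total_intra, self.total) if self.total else "N/A"))
        return out


def compute_cluster_stats(clusters: Sequence[InteractionCluster],
                          min_count: int = 2) -> ClusterStats:
    """Bin clusters by PET count (2..9, >=10) and intra-chromosomal span."""
    stats = ClusterStats(
        by_pet_count={b: {"total": 0, "intra": 0, "inter": 0} for b in PET_COUNT_BINS},
        span_table={b: 0 for b in SPAN_BINS},
    )
    for c in clusters:
        if c.count < min_count:
            continue
        b = _pet_count_bin(c.count)
        stats.by_pet_count[b]["total"] += 1
        stats.by_pet_count[b]["intra" if c.is_intra else "inter"] += 1
        stats.span_table[_span_bin(c)] += 1
    stats.validate()
    return stats


# ---------------------------------------------------------------------------
# Rendering

_SPAN_LABELS = {
    "lt100kb": "<100 kb", "100kb_1Mb": "[100 kb, 1 Mb)", "1Mb_10Mb": "[1 Mb, 10 Mb)",
    "gt10Mb": ">=10 Mb", "inter": "Different chromosomes",
}

_HTML_SHELL = """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>ChIA-PET library report</title>
<style>
body {{ font-family: sans-serif; margin: 2em; }}
table {{ border-collapse: collapse; margin: 1em 0; }}
td, th {{ border: 1px solid #999; padding: 4px 10px; text-align: right; }}
th {{ background: #eee; }} td:first-child, th:first-child {{ text-align: left; }}
</style></head><body>
<h1>ChIA-PET library report</h1>
{body}
</body></html>
"""


def _html_table(title: str, header, rows) -> str:
    head = "".join(f"<th>{h}</th>" for h in header)
    body = "\n".join(
        "<tr>" + "".join(f"<td>{v}</td>" for v in row) + "</tr>" for row in rows)
    return f"<h2>{title}</h2>\n<table><tr>{head}</tr>\n{body}\n</table>"


def _write_tsv(path, header, rows) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(v) for v in row) + "\n")


def render_report(library_stats: LibraryStats,
                  cluster_stats: Optional[ClusterStats],
                  out_dir,
                  plots: Sequence = (),
                  span_rows: Optional[Sequence] = None) -> Path:
    """Write report.html plus machine-readable TSV tables into ``out_dir``.

    ``plots`` holds (title, png bytes) pairs inlined into the HTML. Library
    invariants are re-validated before anything is written; a violation
    aborts with a reconciliation diff.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    library_stats.validate()
    if cluster_stats is not None:
        cluster_stats.validate()

    lib_rows = [(label, value, order) for label, value, order in library_stats.rows()]
    _write_tsv(out_dir / "library_stats.tsv",
               ("category", "number", "order"), lib_rows)
    quality_rows = library_stats.quality_rows()
    _write_tsv(out_dir / "library_quality.tsv", ("category", "amount"), quality_rows)

    sections = [
        _html_table("Stage statistics", ("Category", "Number", "Order"), lib_rows),
        _html_table("Library quality", ("Category", "Amount"), quality_rows),
    ]

    if cluster_stats is not None:
        crows = cluster_stats.rows()
        _write_tsv(out_dir / "cluster_stats.tsv",
                   ("pet_count", "total", "intra", "inter", "pct_intra"), crows)
        sections.append(_html_table(
            "Interaction clusters by PET count",
            ("PET count", "Clusters", "Intra", "Inter", "% intra"), crows))
        srows = [(_SPAN_LABELS[b], cluster_stats.span_table[b],
                  "Intra-chromosomal" if b != "inter" else "Inter-chromosomal")
                 for b in SPAN_BINS]
        _write_tsv(out_dir / "span_distribution.tsv",
                   ("distance", "frequency", "interaction_type"), srows)
        sections.append(_html_table(
            "Span distribution of interactions",
            ("Distance", "Frequency", "Type"), srows))

    if span_rows:
        _write_tsv(out_dir / "span_histogram.tsv",
                   ("bin_low", "bin_high", "++", "+-", "-+", "--"), span_rows)

    for title, png in plots:
        b64 = base64.b64encode(png).decode()
        sections.append(f"<h2>{title}</h2>\n<img src='data:image/png;base64,{b64}'/>")

    html_path = out_dir / "report.html"
    html_path.write_text(_HTML_SHELL.format(body="\n".join(sections)))
    return html_path


def span_distribution_plot(dists) -> bytes:
    """Log-log span-distribution plot (one line per strand composition)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    centers = (dists.bin_edges[:-1] * dists.bin_edges[1:]) ** 0.5
    for comp, counts in dists.counts.items():
        ax.plot(centers, counts, label=comp, lw=1)
    ax.set_xscale("log")
    ax.set_yscale("symlog")
    ax.set_xlabel("genomic span (bp)")
    ax.set_ylabel("PET count")
    ax.legend(title="strand composition")
    buf = io.BytesIO()
    fig.savefig(buf, format="png", dpi=90)
    plt.close(fig)
    return buf.getvalue()
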