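"""Euclidean-distance (ED) association scan and candidate-region calling.

At each biallelic SNP the two bulks yield alternate-allele frequencies
``f_mut`` and ``f_wt``.  The ED statistic is the Euclidean distance between
the two allele-frequency vectors over both allele classes,

    ED = sqrt((f_mut - f_wt)^2 + ((1 - f_mut) - (1 - f_wt))^2)
       = sqrt(2) * |f_mut - f_wt|,

so it ranges from 0 (no divergence between bulks) to sqrt(2) (fixed for
opposite alleles).  Raising ED to a power k (default 5) suppresses the
sampling-noise background while preserving linked peaks.  Sites whose
powered ED exceeds a genome-wide empirical quantile (default 99.5%) are
clustered into candidate regions; a region must hold a minimum number of
above-threshold sites (default 10) to be reported.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .variant_io import BulkVariant

__all__ = [
    "EDPoint",
    "ScanConfig",
    "CandidateRegion",
    "RegionTotals",
    "allele_frequency",
    "ed_statistic",
    "power_transform",
    "compute_ed_points",
    "call_threshold",
    "flag_points",
    "call_regions",
    "region_summary",
    "points_to_frame",
    "regions_to_frame",
    "regions_to_bed",
    "manhattan_plot",
]

SQRT2 = math.sqrt(2.0)


@dataclass(frozen=True)
class EDPoint:
    """Per-SNP bulk frequencies and (powered) ED value.

    Carries the underlying allele identities and depths so that downstream
    zygosity filtering does not need to re-join against the VCF.
    """

    chrom: str
    pos: int
    f_mut: float
    f_wt: float
    ed: float
    ed_k: float
    above: bool | None = None
    ref: str = "N"
    alt: str = "N"
    ad_mut: tuple[int, int] = (0, 0)
    ad_wt: tuple[int, int] = (0, 0)


@dataclass(frozen=True)
class ScanConfig:
    """Scan parameters.

    k
        Exponent of the power transform applied to ED (default 5, the
        convention of the ED BSA-seq literature).
    threshold_quantile
        Genome-wide empirical quantile of the powered ED used as the
        significance threshold (default 0.995).
    min_sites
        Minimum above-threshold sites for a cluster to be reported as a
        candidate region (default 10).
    merge_gap_bp
        Maximum gap between consecutive above-threshold sites joined into
        one cluster (default 1 Mb).
    smoothing / window_bp
        Optional physical-distance moving average of the powered ED
        ("moving_average"); default "none" — all defaults scan unsmoothed.
    per_chromosome
        Compute the threshold per chromosome instead of genome-wide
        (default False).
    """

    k: int = 5
    threshold_quantile: float = 0.995
    min_sites: int = 10
    merge_gap_bp: int = 1_000_000
    smoothing: str = "none"
    window_bp: int = 1_000_000
    per_chromosome: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.threshold_quantile < 1:
            raise ValueError("threshold_quantile must be in (0, 1)")
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.min_sites < 1:
            raise ValueError("min_sites must be >= 1")
        if self.smoothing not in ("none", "moving_average"):
            raise ValueError(f"unknown smoothing mode {self.smoothing!r}")


@dataclass(frozen=True)
class CandidateRegion:
    """An above-threshold genomic interval (1-based inclusive endpoints)."""

    chrom: str
    start_bp: int
    end_bp: int
    n_above: int
    n_total: int
    peak_ed: float
    n_genes: int | None = None
    n_transcripts: int | None = None

    def __post_init__(self) -> None:
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def size_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start_bp <= pos <= self.end_bp


@dataclass(frozen=True)
class RegionTotals:
    n_regions: int
    total_size_mb: float
    total_genes: int
    total_transcripts: int


def allele_frequency(ad: tuple[int, int]) -> float:
    """Alternate-allele frequency ``alt / (ref + alt)`` from an AD tuple."""
    total = ad[0] + ad[1]
    if total <= 0:
        raise ValueError("allele frequency undefined at zero total depth")
    return ad[1] / total


def ed_statistic(f_mut: float, f_wt: float) -> float:
    """ED between bulk allele-frequency vectors; equals sqrt(2)*|f_mut - f_wt|."""
    for f in (f_mut, f_wt):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"frequency {f} outside [0, 1]")
    d_alt = f_mut - f_wt
    d_ref = (1.0 - f_mut) - (1.0 - f_wt)
    return math.sqrt(d_alt * d_alt + d_ref * d_ref)


def power_transform(ed: float, k: int) -> float:
    """Raise ED to the k-th power (monotone background suppression)."""
    if ed < 0:
        raise ValueError("ed must be >= 0")
    return ed**k


def compute_ed_points(variants: Sequence[BulkVariant], cfg: ScanConfig | None = None) -> list[EDPoint]:
    """Compute per-SNP frequencies and (powered) ED for filtered variants.

    Optionally applies the configured physical-distance moving average to
    the powered ED within each chromosome.
    """
    cfg = cfg or ScanConfig()
    points = []
    for v in variants:
        f_mut = allele_frequency(v.ad_mut)
        f_wt = allele_frequency(v.ad_wt)
        ed = ed_statistic(f_mut, f_wt)
        points.append(
            EDPoint(
                chrom=v.chrom,
                pos=v.pos,
                f_mut=f_mut,
                f_wt=f_wt,
                ed=ed,
                ed_k=power_transform(ed, cfg.k),
                ref=v.ref,
                alt=v.alt,
                ad_mut=v.ad_mut,
                ad_wt=v.ad_wt,
            )
        )
    if cfg.smoothing == "moving_average":
        points = _smooth_moving_average(points, cfg.window_bp)
    return points


def _smooth_moving_average(points: list[EDPoint], window_bp: int) -> list[EDPoint]:
    """Replace each site's ed_k by the mean over sites within +-window_bp/2."""
    half = window_bp / 2
    out: list[EDPoint] = []
    by_chrom: dict[str, list[EDPoint]] = {}
    for p in points:
        by_chrom.setdefault(p.chrom, []).append(p)
    for chrom_points in by_chrom.values():
        pos = np.array([p.pos for p in chrom_points], dtype=float)
        edk = np.array([p.ed_k for p in chrom_points], dtype=float)
        lo = np.searchsorted(pos, pos - half, side="left")
        hi = np.searchsorted(pos, pos + half, side="right")
        csum = np.concatenate([[0.0], np.cumsum(edk)])
        smoothed = (csum[hi] - csum[lo]) / (hi - lo)
        out.extend(replace(p, ed_k=float(s)) for p, s in zip(chrom_points, smoothed))
    out.sort(key=lambda p: (p.chrom, p.pos))
    return out


def call_threshold(values: Iterable[float], q: float) -> float:
    """Empirical q-quantile (linear interpolation between order statistics)."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size == 0:
        raise ValueError("cannot compute a quantile of no values")
    return float(np.quantile(arr, q, method="linear"))


def flag_points(points: Sequence[EDPoint], threshold: float) -> list[EDPoint]:
    """Return points with the ``above`` flag set against ``threshold``."""
    return [replace(p, above=p.ed_k > threshold) for p in points]


def _check_sorted(points: Sequence[EDPoint]) -> None:
    seen: set[str] = set()
    prev_chrom = None
    prev_pos = -1
    for p in points:
        if p.chrom != prev_chrom:
            if p.chrom in seen:
                raise ValueError("points not grouped by chromosome")
            seen.add(p.chrom)
            prev_chrom = p.chrom
            prev_pos = -1
        if p.pos < prev_pos:
            raise ValueError(f"points not sorted by position at {p.chrom}:{p.pos}")
        prev_pos = p.pos


def call_regions(points: Sequence[EDPoint], threshold: float, cfg: ScanConfig | None = None) -> list[CandidateRegion]:
    """Cluster above-threshold sites into candidate regions.

    Consecutive above-threshold sites on the same chromosome are joined when
    their gap is at most ``merge_gap_bp``; a cluster is reported when it
    holds at least ``min_sites`` above-threshold sites, spanning its first
    to last above-threshold site.  Input must be sorted by (chrom, pos).
    """
    cfg = cfg or ScanConfig()
    _check_sorted(points)
    flagged = flag_points(points, threshold)

    regions: list[CandidateRegion] = []
    cluster: list[EDPoint] = []

    def flush() -> None:
        if len(cluster) >= cfg.min_sites:
            start, end = cluster[0].pos, cluster[-1].pos
            chrom = cluster[0].chrom
            in_span = [p for p in flagged if p.chrom == chrom and start <= p.pos <= end]
            regions.append(
                CandidateRegion(
                    chrom=chrom,
                    start_bp=start,
                    end_bp=end,
                    n_above=len(cluster),
                    n_total=len(in_span),
                    peak_ed=max(p.ed_k for p in in_span),
                )
            )
        cluster.clear()

    for p in flagged:
        if not p.above:
            continue
        if cluster and (p.chrom != cluster[-1].chrom or p.pos - cluster[-1].pos > cfg.merge_gap_bp):
            flush()
        cluster.append(p)
    flush()
    return regions


def region_summary(
    regions: Sequence[CandidateRegion],
    annotations: Sequence[tuple[int, int]] | None = None,
) -> RegionTotals:
    """Totals over a region list: count, summed size (Mb), genes, transcripts.

    ``annotations``, when given, supplies per-region ``(n_genes,
    n_transcripts)`` pairs overriding any counts stored on the regions.
    """
    if annotations is not None:
        if len(annotations) != len(regions):
            raise ValueError("annotations must match regions one-to-one")
        genes = sum(a[0] for a in annotations)
        transcripts = sum(a[1] for a in annotations)
    else:
        genes = sum(r.n_genes or 0 for r in regions)
        transcripts = sum(r.n_transcripts or 0 for r in regions)
    total_bp = sum(r.end_bp - r.start_bp for r in regions)
    return RegionTotals(
        n_regions=len(regions),
        total_size_mb=total_bp / 1e6,
        total_genes=genes,
        total_transcripts=transcripts,
    )


def points_to_frame(points: Sequence[EDPoint]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [p.chrom for p in points],
            "pos": [p.pos for p in points],
            "f_mut": [p.f_mut for p in points],
            "f_wt": [p.f_wt for p in points],
            "ed": [p.ed for p in points],
            "ed_k": [p.ed_k for p in points],
            "above": [p.above for p in points],
        }
    )


def regions_to_frame(regions: Sequence[CandidateRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start_bp": [r.start_bp for r in regions],
            "end_bp": [r.end_bp for r in regions],
            "size_mb": [r.size_mb for r in regions],
            "n_above": [r.n_above for r in regions],
            "n_total": [r.n_total for r in regions],
            "peak_ed": [r.peak_ed for r in regions],
            "n_genes": [r.n_genes for r in regions],
            "n_transcripts": [r.n_transcripts for r in regions],
        }
    )


def regions_to_bed(regions: Sequence[CandidateRegion], path: str | os.PathLike) -> str:
    """Write regions as BED (0-based half-open)."""
    path = os.fspath(path)
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start_bp - 1}\t{r.end_bp}\tn_above={r.n_above}\n")
    return path


def manhattan_plot(
    points: Sequence[EDPoint],
    regions: Sequence[CandidateRegion],
    threshold: float,
    out_path: str | os.PathLike,
) -> str:
    """Per-chromosome scatter of powered ED with threshold line and shaded regions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not points:
        raise ValueError("no points to plot")
    chroms = sorted({p.chrom for p in points})
    lengths = {c: max(p.pos for p in points if p.chrom == c) for c in chroms}
    offsets: dict[str, float] = {}
    running = 0.0
    for c in chroms:
        offsets[c] = running
        running += lengths[c] * 1.02

    fig, ax = plt.subplots(figsize=(10, 3.2))
    cycle = plt.rcParams["axes.prop_cycle"].by_key()["color"]
    for i, c in enumerate(chroms):
        xs = [offsets[c] + p.pos for p in points if p.chrom == c]
        ys = [p.ed_k for p in points if p.chrom == c]
        ax.scatter(xs, ys, s=4, color=cycle[i % len(cycle)], label=c)
    for r in regions:
        ax.axvspan(offsets[r.chrom] + r.start_bp, offsets[r.chrom] + r.end_bp, color="red", alpha=0.15)
    ax.axhline(threshold, color="red", linestyle="--", linewidth=1)
    ax.set_xticks([offsets[c] + lengths[c] / 2 for c in chroms])
    ax.set_xticklabels(chroms)
    ax.set_xlabel("chromosome")
    ax.set_ylabel("powered ED")
    fig.tight_layout()
    out_path = os.fspath(out_path)
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return out_path
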