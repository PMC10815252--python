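"""End-to-end orchestration: simulate/ingest -> scan -> regions -> candidates."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .candidate_filter import ZygosityConfig, candidate_snps, zygosity_filter
from .ed_scan import (
    CandidateRegion,
    EDPoint,
    ScanConfig,
    call_regions,
    call_threshold,
    compute_ed_points,
    flag_points,
)
from .effect_annotator import GeneModel, annotate_variants
from .simulate import SimConfig, SimResult, simulate_experiment
from .variant_io import BulkVariant, FilterConfig, filter_variants

__all__ = ["ScanResult", "scan_variants", "PipelineResult", "run_pipeline"]

log = logging.getLogger("edmap")


@dataclass
class ScanResult:
    points: list[EDPoint]
    threshold: float
    regions: list[CandidateRegion]
    n_input: int
    n_retained: int


def scan_variants(
    variants: Sequence[BulkVariant],
    filter_cfg: FilterConfig | None = None,
    scan_cfg: ScanConfig | None = None,
) -> ScanResult:
    """Filter variants, compute (powered) ED, set the threshold, call regions."""
    filter_cfg = filter_cfg or FilterConfig()
    scan_cfg = scan_cfg or ScanConfig()
    retained = filter_variants(variants, filter_cfg)
    log.info("filter: %d in, %d retained, %d dropped", len(variants), len(retained), len(variants) - len(retained))
    if not retained:
        raise ValueError("no variants pass filtering; nothing to scan")
    points = compute_ed_points(retained, scan_cfg)
    if scan_cfg.per_chromosome:
        thresholds = {}
        chroms = {p.chrom for p in points}
        flagged: list[EDPoint] = []
        regions: list[CandidateRegion] = []
        for chrom in sorted(chroms):
            sub = [p for p in points if p.chrom == chrom]
            thr = call_threshold([p.ed_k for p in sub], scan_cfg.threshold_quantile)
            thresholds[chrom] = thr
            flagged.extend(flag_points(sub, thr))
            regions.extend(call_regions(sub, thr, scan_cfg))
        threshold = max(thresholds.values())
        points = flagged
    else:
        threshold = call_threshold([p.ed_k for p in points], scan_cfg.threshold_quantile)
        points = flag_points(points, threshold)
        regions = call_regions(points, threshold, scan_cfg)
    log.info("scan: threshold %.6g, %d above, %d regions", threshold, sum(p.above for p in points), len(regions))
    return ScanResult(
        points=points,
        threshold=threshold,
        regions=regions,
        n_input=len(variants),
        n_retained=len(retained),
    )


@dataclass
class PipelineResult:
    sim: SimResult | None
    scan: ScanResult
    survivors: list[EDPoint]
    candidates: pd.DataFrame

    def causal_in_region(self) -> bool:
        c = self.sim.config.causal
        return any(r.contains(c.chrom, c.pos) for r in self.scan.regions)

    def causal_ranked_first(self) -> bool:
        c = self.sim.config.causal
        if not len(self.candidates):
            return False
        top = self.candidates.iloc[0]
        return top.chrom == c.chrom and int(top.pos) == c.pos


def run_pipeline(
    sim_cfg: SimConfig,
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
    filter_cfg: FilterConfig | None = None,
    scan_cfg: ScanConfig | None = None,
    zyg_cfg: ZygosityConfig | None = None,
    out_dir=None,
) -> PipelineResult:
    """Simulated experiment through to the ranked candidate-SNP table.

    ``models``/``genome`` come from a gene-annotation fixture built around
    the configured causal SNP (see :func:`edmap.simulate.make_gene_fixture`),
    so only one fixture load is needed across replicates.
    """
    zyg_cfg = zyg_cfg or ZygosityConfig(
        mode="dominant" if sim_cfg.inheritance == "dominant" else "recessive"
    )
    sim = simulate_experiment(sim_cfg, out_dir=out_dir)
    scan = scan_variants(sim.variants, filter_cfg, scan_cfg)
    survivors = zygosity_filter(scan.points, scan.regions, zyg_cfg)
    log.info("zygosity: %d in regions+windows", len(survivors))
    as_variants = [
        BulkVariant(
            chrom=p.chrom, pos=p.pos, ref=p.ref, alt=p.alt, ad_mut=p.ad_mut, ad_wt=p.ad_wt
        )
        for p in survivors
    ]
    effects = annotate_variants(as_variants, models, genome)
    candidates = candidate_snps(survivors, effects, scan.regions, zyg_cfg)
    log.info("candidates: %d ranked", len(candidates))
    return PipelineResult(sim=sim, scan=scan, survivors=survivors, candidates=candidates)
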