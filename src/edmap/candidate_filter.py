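"""Zygosity- and effect-based selection of candidate causal SNPs.

For a dominant induced mutation mapped in an F2, the mutant-phenotype bulk
is a 1:2 mixture of homozygous and heterozygous carriers, so the causal
alternate-allele frequency concentrates near 2/3 there, while the
wild-phenotype bulk is homozygous reference (frequency ~0).  A recessive
design instead fixes the causal allele in the mutant bulk (frequency ~1).
SNPs inside candidate regions are kept when their bulk frequencies match
the expected pattern for the configured inheritance mode, then intersected
with damaging predicted effects and ranked by powered ED.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .ed_scan import CandidateRegion, EDPoint
from .effect_annotator import EffectCall

__all__ = ["ZygosityConfig", "zygosity_filter", "candidate_snps"]

DEFAULT_EFFECTS_KEPT = frozenset(
    {"missense", "nonsense", "start_lost", "stop_lost", "splice_site"}
)

#: EMS mutagenesis induces almost exclusively G:C -> A:T transitions.
EMS_CHANGES = frozenset({("G", "A"), ("C", "T")})


@dataclass(frozen=True)
class ZygosityConfig:
    """Bulk-frequency windows expected of the causal SNP.

    mode
        "dominant": mutant bulk heterozygous mixture, window [0.4, 0.85]
        around the 2/3 expectation; "recessive": causal allele nearly fixed,
        window [0.9, 1.0].
    wt_max_freq
        Maximum alternate-allele frequency tolerated in the wild-phenotype
        bulk (default 0.1).
    min_depth
        Minimum total depth per bulk at a candidate site (default 10).
    effects_kept
        Predicted-consequence classes retained as candidates.
    ems_spectrum_only
        Restrict candidates to the EMS G>A / C>T spectrum (default off).
    """

    mode: str = "dominant"
    wt_max_freq: float = 0.1
    mut_freq_window: tuple[float, float] | None = None
    min_depth: int = 10
    effects_kept: frozenset[str] = DEFAULT_EFFECTS_KEPT
    ems_spectrum_only: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mut_freq_window is None:
            window = (0.4, 0.85) if self.mode == "dominant" else (0.9, 1.0)
            object.__setattr__(self, "mut_freq_window", window)
        lo, hi = self.mut_freq_window
        if not 0 <= self.wt_max_freq < lo < hi <= 1:
            raise ValueError(
                "require 0 <= wt_max_freq < mut_freq_window.low < "
                f"mut_freq_window.high <= 1, got {self.wt_max_freq}, {lo}, {hi}"
            )

    def passes(self, p: EDPoint) -> bool:
        if sum(p.ad_mut) < self.min_depth or sum(p.ad_wt) < self.min_depth:
            return False
        lo, hi = self.mut_freq_window
        if not (p.f_wt <= self.wt_max_freq and lo <= p.f_mut <= hi):
            return False
        if self.ems_spectrum_only and (p.ref, p.alt) not in EMS_CHANGES:
            return False
        return True


def zygosity_filter(
    points: Sequence[EDPoint],
    regions: Sequence[CandidateRegion],
    cfg: ZygosityConfig | None = None,
) -> list[EDPoint]:
    """SNPs inside candidate regions whose bulk frequencies fit the mode.

    Returns survivors sorted by powered ED descending, ties broken by
    (chrom, pos).
    """
    cfg = cfg or ZygosityConfig()
    survivors = [
        p
        for p in points
        if any(r.contains(p.chrom, p.pos) for r in regions) and cfg.passes(p)
    ]
    survivors.sort(key=lambda p: (-p.ed_k, p.chrom, p.pos))
    return survivors


def candidate_snps(
    filtered: Sequence[EDPoint],
    effects: Sequence[EffectCall],
    regions: Sequence[CandidateRegion] = (),
    cfg: ZygosityConfig | None = None,
) -> pd.DataFrame:
    """Rank zygosity survivors carrying a damaging predicted effect.

    ``effects`` must cover every SNP in ``filtered`` (keyed by chrom, pos).
    Returns a table sorted by powered ED descending (ties by chrom, pos)
    with columns region, chrom, pos, ref, alt, effect, short_form, ed_k.
    """
    cfg = cfg or ZygosityConfig()
    by_site = {(e.variant.chrom, e.variant.pos): e for e in effects}
    rows = []
    for p in filtered:
        eff = by_site.get((p.chrom, p.pos))
        if eff is None:
            raise KeyError(f"no effect annotation for {p.chrom}:{p.pos}")
        if eff.effect not in cfg.effects_kept:
            continue
        region = next(
            (f"{r.chrom}:{r.start_bp}-{r.end_bp}" for r in regions if r.contains(p.chrom, p.pos)),
            None,
        )
        rows.append(
            {
                "region": region,
                "chrom": p.chrom,
                "pos": p.pos,
                "ref": p.ref,
                "alt": p.alt,
                "effect": eff.effect,
                "short_form": eff.short_form,
                "ed_k": p.ed_k,
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=["region", "chrom", "pos", "ref", "alt", "effect", "short_form", "ed_k"],
    )
    if len(frame):
        frame = frame.sort_values(
            ["ed_k", "chrom", "pos"], ascending=[False, True, True], kind="mergesort"
        ).reset_index(drop=True)
    return frame
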