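"""Read, filter and write pooled-bulk variant data.

Bulked-segregant experiments sequence two DNA pools — one per contrasting
phenotype class — and the downstream association scan only needs, per
biallelic SNP, the (ref, alt) read counts observed in each pool.  This module
maps a two-sample VCF (one sample per bulk, allelic depths in the ``AD``
FORMAT field) onto that minimal data model and applies conventional
depth/quality filters.

Coordinates are 1-based throughout, as in VCF; BED exports elsewhere use
0-based half-open intervals.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "BulkVariant",
    "FilterConfig",
    "SampleNotFoundError",
    "AllelicDepthError",
    "read_bulk_vcf",
    "filter_variants",
    "write_bulk_vcf",
    "variants_to_frame",
]


class SampleNotFoundError(KeyError):
    """A requested sample name is absent from the VCF header."""


class AllelicDepthError(ValueError):
    """A VCF record lacks a usable per-sample allelic-depth (AD) field."""


@dataclass(frozen=True)
class BulkVariant:
    """One called variant with allelic depths in both phenotype bulks.

    ``ad_mut``/``ad_wt`` are ``(ref_count, alt_count)`` tuples for the
    mutant-phenotype and wild-phenotype bulk respectively.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ad_mut: tuple[int, int]
    ad_wt: tuple[int, int]
    qual: float | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for ad in (self.ad_mut, self.ad_wt):
            if min(ad) < 0:
                raise ValueError(f"negative allelic depth {ad} at {self.chrom}:{self.pos}")

    @property
    def depth_mut(self) -> int:
        return self.ad_mut[0] + self.ad_mut[1]

    @property
    def depth_wt(self) -> int:
        return self.ad_wt[0] + self.ad_wt[1]

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class FilterConfig:
    """Variant retention rules applied before the association scan.

    min_depth_per_bulk
        Minimum total read depth required in *each* bulk (default 10).
    min_qual
        Minimum variant quality; records without a QUAL value pass this
        check (default 30).
    biallelic_snv_only
        Keep only single-base ref/alt records (default True); indels are
        parsed upstream but excluded from the scan.
    """

    min_depth_per_bulk: int = 10
    min_qual: float = 30.0
    biallelic_snv_only: bool = True

    def __post_init__(self) -> None:
        if self.min_depth_per_bulk < 0:
            raise ValueError("min_depth_per_bulk must be >= 0")

    def passes(self, v: BulkVariant) -> bool:
        if v.depth_mut < self.min_depth_per_bulk or v.depth_wt < self.min_depth_per_bulk:
            return False
        if v.qual is not None and v.qual < self.min_qual:
            return False
        if self.biallelic_snv_only and not v.is_snv:
            return False
        return True


def read_bulk_vcf(path: str | os.PathLike, mut_sample: str, wt_sample: str) -> list[BulkVariant]:
    """Read a two-bulk VCF into :class:`BulkVariant` records.

    One record is produced per VCF row, in file order, using the first ALT
    allele.  Each named sample must carry an ``AD`` FORMAT field.

    Raises
    ------
    SampleNotFoundError
        if either sample name is missing from the header.
    AllelicDepthError
        if a record lacks the AD field, naming the offending record.
    OSError
        if the file cannot be read.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise OSError(f"cannot read VCF: {path}")
    vcf = VCF(path)
    try:
        samples = list(vcf.samples)
        for name in (mut_sample, wt_sample):
            if name not in samples:
                raise SampleNotFoundError(
                    f"sample {name!r} not in VCF header (samples: {samples})"
                )
        i_mut = samples.index(mut_sample)
        i_wt = samples.index(wt_sample)

        out: list[BulkVariant] = []
        for rec in vcf:
            try:
                ad = rec.format("AD")
            except KeyError:
                ad = None
            if ad is None:
                raise AllelicDepthError(
                    f"record {rec.CHROM}:{rec.POS} has no AD (allelic depth) field"
                )
            alt = rec.ALT[0] if rec.ALT else "."
            out.append(
                BulkVariant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    ad_mut=(max(int(ad[i_mut][0]), 0), max(int(ad[i_mut][1]), 0)),
                    ad_wt=(max(int(ad[i_wt][0]), 0), max(int(ad[i_wt][1]), 0)),
                    qual=None if rec.QUAL is None else float(rec.QUAL),
                )
            )
        return out
    finally:
        vcf.close()


def filter_variants(variants: Iterable[BulkVariant], cfg: FilterConfig | None = None) -> list[BulkVariant]:
    """Retain variants passing all :class:`FilterConfig` predicates, order preserved."""
    cfg = cfg or FilterConfig()
    return [v for v in variants if cfg.passes(v)]


_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=edmap
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths for the ref and alt alleles">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_bulk_vcf(
    variants: Sequence[BulkVariant],
    path: str | os.PathLike,
    mut_sample: str = "MUT",
    wt_sample: str = "WT",
    contig_lengths: dict[str, int] | None = None,
) -> str:
    """Write variants as a minimal two-sample VCF 4.2 file.

    Output is plain text and byte-deterministic for a given input, which the
    seeded-simulation contract relies on.  Round-trips through
    :func:`read_bulk_vcf`.
    """
    path = os.fspath(path)
    if contig_lengths is None:
        contig_lengths = {}
        for v in variants:
            contig_lengths[v.chrom] = max(contig_lengths.get(v.chrom, 0), v.pos)
    lines = [_VCF_HEADER]
    for chrom, length in contig_lengths.items():
        lines.append(f"##contig=<ID={chrom},length={length}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
        f"{mut_sample}\t{wt_sample}\n"
    )
    for v in variants:
        qual = "." if v.qual is None else f"{v.qual:g}"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t{qual}\t.\t.\tAD:DP\t"
            f"{v.ad_mut[0]},{v.ad_mut[1]}:{v.depth_mut}\t"
            f"{v.ad_wt[0]},{v.ad_wt[1]}:{v.depth_wt}\n"
        )
    with open(path, "w") as fh:
        fh.writelines(lines)
    return path


def variants_to_frame(variants: Sequence[BulkVariant]) -> pd.DataFrame:
    """Tabulate variants (one row per SNP) for TSV export."""
    return pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [v.alt for v in variants],
            "mut_ref": [v.ad_mut[0] for v in variants],
            "mut_alt": [v.ad_mut[1] for v in variants],
            "wt_ref": [v.ad_wt[0] for v in variants],
            "wt_alt": [v.ad_wt[1] for v in variants],
        }
    )
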