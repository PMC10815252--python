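"""Codon-level SNP consequence annotation against GFF3 gene models.

A deliberately small annotator for single-nucleotide substitutions: each SNP
is placed in its gene context (CDS / splice site / intron / intergenic) and,
when coding, the affected codon is rebuilt from the spliced CDS —
phase-aware across exon junctions and reverse-complemented on the minus
strand — and translated with the standard nuclear genetic code.  When a SNP
overlaps several transcripts the single most severe consequence is reported
(nonsense > start_lost > stop_lost > missense > splice_site > synonymous >
intronic > intergenic).

Coordinates are GFF3 1-based inclusive; amino-acid positions count the
initiator Met as 1, so a Gly-to-Ser change at residue 217 prints "G217S".
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import gffutils
from Bio.Seq import Seq

from .variant_io import BulkVariant

__all__ = [
    "Transcript",
    "GeneModel",
    "EffectCall",
    "ReferenceMismatchError",
    "SEVERITY_ORDER",
    "SPLICE_WINDOW",
    "load_fasta",
    "load_gene_models",
    "annotate_variant",
    "annotate_variants",
    "effects_to_frame",
]

# most severe first; "unknown" (ambiguity code in codon) sorts below coding calls
SEVERITY_ORDER = [
    "nonsense",
    "start_lost",
    "stop_lost",
    "missense",
    "splice_site",
    "synonymous",
    "unknown",
    "intronic",
    "intergenic",
]
_SEVERITY_RANK = {name: i for i, name in enumerate(SEVERITY_ORDER)}

SPLICE_WINDOW = 2  # bp into the intron flanking each exon boundary (GT-AG rule)

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the genome base at its position."""


@dataclass(frozen=True)
class Transcript:
    """Ordered exon and CDS intervals of one mRNA (1-based inclusive)."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        for name, ivals in (("exons", self.exons), ("cds", self.cds)):
            for (s, e) in ivals:
                if s > e:
                    raise ValueError(f"{name} interval ({s}, {e}) inverted")
        for a, b in zip(self.exons, self.exons[1:]):
            if b[0] <= a[1]:
                raise ValueError("exons must be sorted and non-overlapping")

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    strand: str
    transcripts: tuple[Transcript, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        starts, ends = zip(*(t.span for t in self.transcripts))
        return min(starts), max(ends)


@dataclass(frozen=True)
class EffectCall:
    """Predicted consequence of one SNP; ``short_form`` like ``G217S`` when coding."""

    variant: BulkVariant
    gene_id: str | None
    effect: str
    codon_index: int | None = None
    ref_aa: str | None = None
    alt_aa: str | None = None

    @property
    def short_form(self) -> str | None:
        if self.codon_index is None or self.ref_aa is None or self.alt_aa is None:
            return None
        return f"{self.ref_aa}{self.codon_index}{self.alt_aa}"

    @property
    def severity_rank(self) -> int:
        return _SEVERITY_RANK[self.effect]


def load_fasta(fasta_path: str | os.PathLike) -> dict[str, str]:
    """Load a FASTA into a {contig: uppercase sequence} dict."""
    from Bio import SeqIO

    return {
        rec.id: str(rec.seq).upper()
        for rec in SeqIO.parse(os.fspath(fasta_path), "fasta")
    }


def load_gene_models(
    gff_path: str | os.PathLike, fasta_path: str | os.PathLike
) -> tuple[list[GeneModel], dict[str, str]]:
    """Parse GFF3 gene/mRNA/exon/CDS features and the genome FASTA.

    Validates that every model sits on a known contig within its bounds.
    A complete model whose CDS length is not a multiple of 3 triggers a
    warning, not an error.
    """
    genome = load_fasta(fasta_path)
    try:
        db = gffutils.create_db(
            os.fspath(gff_path),
            ":memory:",
            merge_strategy="create_unique",
            keep_order=True,
        )
    except gffutils.exceptions.EmptyInputError:
        return [], genome
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        if gene.seqid not in genome:
            raise ValueError(f"gene {gene.id} on unknown contig {gene.seqid}")
        transcripts = []
        for mrna in db.children(gene, featuretype="mRNA", order_by="start"):
            exons = tuple(
                (f.start, f.end)
                for f in db.children(mrna, featuretype="exon", order_by="start")
            )
            cds = tuple(
                (f.start, f.end)
                for f in db.children(mrna, featuretype="CDS", order_by="start")
            )
            if not exons:
                exons = cds
            contig_len = len(genome[gene.seqid])
            for s, e in exons + cds:
                if s < 1 or e > contig_len:
                    raise ValueError(
                        f"feature ({s}, {e}) of {mrna.id} outside contig "
                        f"{gene.seqid} (length {contig_len})"
                    )
            t = Transcript(transcript_id=mrna.id, exons=exons, cds=cds)
            if t.cds and t.cds_length % 3 != 0:
                warnings.warn(
                    f"CDS length of {mrna.id} ({t.cds_length}) not divisible by 3"
                )
            transcripts.append(t)
        if transcripts:
            models.append(
                GeneModel(
                    gene_id=gene.id,
                    chrom=gene.seqid,
                    strand=gene.strand,
                    transcripts=tuple(transcripts),
                )
            )
    return models, genome


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _spliced_cds(t: Transcript, strand: str, contig: str) -> str:
    """CDS sequence in translation order (5'->3' of the mRNA)."""
    parts = [contig[s - 1 : e] for s, e in t.cds]
    seq = "".join(parts)
    return _revcomp(seq) if strand == "-" else seq


def _cds_offset(t: Transcript, strand: str, pos: int) -> int | None:
    """0-based offset of genomic ``pos`` within the spliced CDS, or None."""
    offset = 0
    total = t.cds_length
    for s, e in t.cds:
        if s <= pos <= e:
            plus_off = offset + (pos - s)
            return total - 1 - plus_off if strand == "-" else plus_off
        offset += e - s + 1
    return None


def _is_splice_site(t: Transcript, pos: int) -> bool:
    """Within SPLICE_WINDOW bp inside an intron, next to an exon boundary."""
    for (s1, e1), (s2, e2) in zip(t.exons, t.exons[1:]):
        intron_start, intron_end = e1 + 1, s2 - 1
        if intron_start > intron_end:
            continue
        if intron_start <= pos <= min(intron_end, intron_start + SPLICE_WINDOW - 1):
            return True
        if max(intron_start, intron_end - SPLICE_WINDOW + 1) <= pos <= intron_end:
            return True
    return False


def _classify_coding(
    t: Transcript, strand: str, contig: str, pos: int, alt: str
) -> EffectCall | None:
    """Build the affected codon and classify; None if pos not in this CDS."""
    off = _cds_offset(t, strand, pos)
    if off is None:
        return None
    cds_seq = _spliced_cds(t, strand, contig)
    codon_i = off // 3
    codon = cds_seq[codon_i * 3 : codon_i * 3 + 3]
    if len(codon) < 3:
        return None  # trailing partial codon on an incomplete model
    alt_base = alt.translate(_COMPLEMENT) if strand == "-" else alt
    within = off % 3
    alt_codon = codon[:within] + alt_base + codon[within + 1 :]
    if any(b not in "ACGT" for b in codon + alt_codon):
        return EffectCall(variant=None, gene_id=None, effect="unknown")  # type: ignore[arg-type]
    ref_aa = str(Seq(codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    if alt_aa == ref_aa:
        effect = "synonymous"
    elif alt_aa == "*":
        effect = "nonsense"
    elif ref_aa == "*":
        effect = "stop_lost"
    elif codon_i == 0 and ref_aa == "M":
        effect = "start_lost"
    else:
        effect = "missense"
    return EffectCall(
        variant=None,  # type: ignore[arg-type]  # filled by caller
        gene_id=None,
        effect=effect,
        codon_index=codon_i + 1,
        ref_aa=ref_aa,
        alt_aa=alt_aa,
    )


def annotate_variant(
    v: BulkVariant,
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> EffectCall:
    """Assign the most severe consequence of a SNP across all gene models.

    The REF allele is checked against the genome base at the position; an
    ``N`` in the assembly skips the check (unassembled/masked sequence) and
    such positions annotate as intergenic unless covered by a model.
    """
    if v.chrom not in genome:
        raise ValueError(f"contig {v.chrom} absent from genome")
    contig = genome[v.chrom]
    if v.pos > len(contig):
        raise ValueError(
            f"position {v.chrom}:{v.pos} beyond contig end ({len(contig)})"
        )
    genome_base = contig[v.pos - 1]
    if genome_base != "N" and len(v.ref) == 1 and genome_base != v.ref.upper():
        raise ReferenceMismatchError(
            f"REF {v.ref!r} at {v.chrom}:{v.pos} does not match genome base {genome_base!r}"
        )

    best: EffectCall | None = None
    for gene in models:
        if gene.chrom != v.chrom:
            continue
        span = gene.span
        if not span[0] <= v.pos <= span[1]:
            continue
        for t in gene.transcripts:
            call = _classify_coding(t, gene.strand, contig, v.pos, v.alt)
            if call is not None:
                call = EffectCall(
                    variant=v,
                    gene_id=gene.gene_id,
                    effect=call.effect,
                    codon_index=call.codon_index,
                    ref_aa=call.ref_aa,
                    alt_aa=call.alt_aa,
                )
            elif _is_splice_site(t, v.pos):
                call = EffectCall(variant=v, gene_id=gene.gene_id, effect="splice_site")
            elif t.span[0] <= v.pos <= t.span[1]:
                # intron or non-coding exon sequence: lumped as intronic
                call = EffectCall(variant=v, gene_id=gene.gene_id, effect="intronic")
            else:
                continue
            if best is None or call.severity_rank < best.severity_rank:
                best = call
    if best is None:
        best = EffectCall(variant=v, gene_id=None, effect="intergenic")
    return best


def annotate_variants(
    variants: Sequence[BulkVariant],
    models: Sequence[GeneModel],
    genome: Mapping[str, str],
) -> list[EffectCall]:
    """Batch annotation; positions outside the assembled reference bundle
    (absent contig, or beyond a contig end) are reported intergenic."""
    out = []
    for v in variants:
        if v.chrom not in genome or v.pos > len(genome[v.chrom]):
            out.append(EffectCall(variant=v, gene_id=None, effect="intergenic"))
        else:
            out.append(annotate_variant(v, models, genome))
    return out


def effects_to_frame(effects: Sequence[EffectCall]):
    import pandas as pd

    return pd.DataFrame(
        {
            "chrom": [e.variant.chrom for e in effects],
            "pos": [e.variant.pos for e in effects],
            "ref": [e.variant.ref for e in effects],
            "alt": [e.variant.alt for e in effects],
            "gene_id": [e.gene_id for e in effects],
            "effect": [e.effect for e in effects],
            "short_form": [e.short_form for e in effects],
        }
    )
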