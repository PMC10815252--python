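"""Forward simulation of a bulked-segregant F2 mapping experiment.

The generator emulates the design of a MutMap-style study of an induced
dominant mutant: a mutagenized line carrying a single causal G-to-A change
is crossed to its wild-type progenitor, the F1 selfed, and an F2 population
phenotyped.  Equal-size bulks of mutant-phenotype and wild-phenotype plants
are pooled and sequenced, and allele counts at every marker are read off as
a two-sample VCF.

Model components:

* Meiosis follows the Haldane map function — crossover counts are Poisson
  with mean ``chrom_length_Mb * cM_per_Mb / 100`` per chromosome and
  breakpoints are uniform, i.e. no interference.
* The two parental lines differ at every marker (fixed alternate alleles),
  so each marker is informative about parental origin, as in a
  mutant x wild-type cross.
* Phenotype is determined by the causal genotype (>= 1 mutant allele under
  dominance, 2 under recessivity), optionally corrupted by a
  misclassification rate (0 by default: phenotyping at the shooting stage
  is unambiguous).
* Sequencing draws a Poisson depth per marker and bulk and binomial
  alternate-allele counts at the true bulk frequency folded with a per-base
  error rate.

All stages consume one :class:`numpy.random.Generator` seeded from
``SimConfig.seed``, so an identical config yields byte-identical output
files.
"""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field
from typing import Sequence

import numpy as np

from .variant_io import BulkVariant, write_bulk_vcf

__all__ = [
    "CausalSpec",
    "SimConfig",
    "F2Genotypes",
    "BulkFrequencies",
    "SimResult",
    "GeneFixture",
    "simulate_f2",
    "make_bulks",
    "simulate_reads",
    "simulate_experiment",
    "make_gene_fixture",
]

_BASES = np.array(list("ACGT"))
_STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class CausalSpec:
    """Location and alleles of the induced causal SNP (EMS-type G>A)."""

    chrom: str = "chr1"
    pos: int = 885_631
    ref: str = "G"
    alt: str = "A"


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic F2 bulk-sequencing experiment.

    Defaults mirror the emulated study design: an F2 of 412 plants scored
    for a dominant mutant phenotype, bulks of 30 plants each, ~40x mean
    pooled depth, and a genome reduced to 2 chromosomes of 50 Mb with
    1,000 markers each (the real organism's 10 chromosomes are reachable
    via ``n_chrom``).
    """

    n_f2: int = 412
    bulk_size: int = 30
    n_chrom: int = 2
    chrom_length_bp: int = 50_000_000
    n_markers: int = 1_000
    causal: CausalSpec = field(default_factory=CausalSpec)
    inheritance: str = "dominant"
    cM_per_Mb: float = 3.0
    mean_depth: float = 40.0
    seq_error: float = 0.001
    misclassification_rate: float = 0.0
    ems_spectrum: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.inheritance not in ("dominant", "recessive"):
            raise ValueError(f"unknown inheritance {self.inheritance!r}")
        if not 1 <= self.causal_chrom_index + 1 <= self.n_chrom:
            raise ValueError(f"causal chromosome {self.causal.chrom} not simulated")
        if not 1 <= self.causal.pos <= self.chrom_length_bp:
            raise ValueError("causal position outside its chromosome")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be > 0")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chrom)]

    @property
    def causal_chrom_index(self) -> int:
        names = [f"chr{i + 1}" for i in range(max(self.n_chrom, 1))]
        if self.causal.chrom not in names:
            return -1
        return names.index(self.causal.chrom)

    def to_json(self, path: str | os.PathLike) -> str:
        path = os.fspath(path)
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
        return path


@dataclass
class F2Genotypes:
    """Per-plant mutant-allele dosage (0/1/2) at every marker."""

    positions: dict[str, np.ndarray]  # chrom -> 1-based marker positions
    genotypes: dict[str, np.ndarray]  # chrom -> (n_f2, n_markers) int8
    causal_chrom: str
    causal_index: int  # column of the causal marker on causal_chrom

    @property
    def causal_genotypes(self) -> np.ndarray:
        return self.genotypes[self.causal_chrom][:, self.causal_index]


@dataclass
class BulkFrequencies:
    """True mutant-allele frequency per marker in each phenotype bulk."""

    positions: dict[str, np.ndarray]
    f_mut: dict[str, np.ndarray]
    f_wt: dict[str, np.ndarray]
    causal_chrom: str
    causal_index: int
    phenotype_counts: tuple[int, int]  # (n_wild_phenotype, n_mutant_phenotype)

    @property
    def causal_f_mut(self) -> float:
        return float(self.f_mut[self.causal_chrom][self.causal_index])

    @property
    def causal_f_wt(self) -> float:
        return float(self.f_wt[self.causal_chrom][self.causal_index])


@dataclass
class SimResult:
    config: SimConfig
    genotypes: F2Genotypes
    bulks: BulkFrequencies
    variants: list[BulkVariant]

    @property
    def causal_variant(self) -> BulkVariant:
        c = self.config.causal
        for v in self.variants:
            if v.chrom == c.chrom and v.pos == c.pos:
                return v
        raise LookupError("causal variant not present in simulated output")


def default_marker_positions(cfg: SimConfig) -> dict[str, np.ndarray]:
    """Evenly spaced markers; the causal position is inserted on its chromosome."""
    out = {}
    step = cfg.chrom_length_bp / cfg.n_markers
    base = np.round((np.arange(cfg.n_markers) + 0.5) * step).astype(np.int64)
    for i, chrom in enumerate(cfg.chrom_names):
        pos = base.copy()
        if chrom == cfg.causal.chrom:
            pos = np.unique(np.append(pos, cfg.causal.pos))
        out[chrom] = pos
    return out


def _simulate_gametes(
    rng: np.random.Generator, n_gametes: int, positions: np.ndarray, length_bp: int, cM_per_Mb: float
) -> np.ndarray:
    """(n_gametes, n_markers) array of parental-origin alleles (0/1)."""
    length_morgan = length_bp / 1e6 * cM_per_Mb / 100.0
    n_cross = rng.poisson(length_morgan, size=n_gametes)
    out = np.empty((n_gametes, positions.size), dtype=np.int8)
    starts = rng.integers(0, 2, size=n_gametes)
    for g in range(n_gametes):
        k = n_cross[g]
        if k == 0:
            out[g] = starts[g]
            continue
        breaks = np.sort(rng.uniform(0, length_bp, size=k))
        segments = np.searchsorted(breaks, positions, side="right")
        out[g] = (starts[g] + segments) % 2
    return out


def simulate_f2(
    cfg: SimConfig,
    rng: np.random.Generator | None = None,
    marker_positions: dict[str, np.ndarray] | None = None,
) -> F2Genotypes:
    """Generate an F2 population from selfed heterozygous F1 parents.

    Each plant receives two independent gametes per chromosome, each a
    crossover mosaic of the two parental haplotypes; the marker genotype is
    the mutant-origin allele dosage.  ``marker_positions`` may override the
    default evenly spaced grid (e.g. to place coincident markers).
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    positions = marker_positions or default_marker_positions(cfg)
    genotypes = {}
    for chrom in cfg.chrom_names:
        pos = np.asarray(positions[chrom], dtype=np.int64)
        g1 = _simulate_gametes(rng, cfg.n_f2, pos, cfg.chrom_length_bp, cfg.cM_per_Mb)
        g2 = _simulate_gametes(rng, cfg.n_f2, pos, cfg.chrom_length_bp, cfg.cM_per_Mb)
        genotypes[chrom] = (g1 + g2).astype(np.int8)
    causal_index = int(np.searchsorted(positions[cfg.causal.chrom], cfg.causal.pos))
    return F2Genotypes(
        positions={c: np.asarray(p, dtype=np.int64) for c, p in positions.items()},
        genotypes=genotypes,
        causal_chrom=cfg.causal.chrom,
        causal_index=causal_index,
    )


def make_bulks(
    genos: F2Genotypes, cfg: SimConfig, rng: np.random.Generator | None = None
) -> BulkFrequencies:
    """Phenotype the F2 and pool equal-size bulks from each phenotype class.

    Under dominance a plant shows the mutant phenotype iff it carries at
    least one causal allele; under recessivity iff it is homozygous.  The
    bulk frequency at a marker is the mutant-allele dosage summed over the
    sampled plants divided by ``2 * bulk_size``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 1)
    g_causal = genos.causal_genotypes
    if cfg.inheritance == "dominant":
        is_mutant = g_causal >= 1
    else:
        is_mutant = g_causal == 2
    if cfg.misclassification_rate > 0:
        flips = rng.random(is_mutant.size) < cfg.misclassification_rate
        is_mutant = np.where(flips, ~is_mutant, is_mutant)
    mut_idx = np.flatnonzero(is_mutant)
    wt_idx = np.flatnonzero(~is_mutant)
    for name, idx in (("mutant", mut_idx), ("wild-type", wt_idx)):
        if idx.size < cfg.bulk_size:
            raise ValueError(
                f"only {idx.size} {name}-phenotype plants; need bulk_size={cfg.bulk_size}"
            )
    mut_bulk = rng.choice(mut_idx, size=cfg.bulk_size, replace=False)
    wt_bulk = rng.choice(wt_idx, size=cfg.bulk_size, replace=False)
    denom = 2.0 * cfg.bulk_size
    f_mut = {c: g[mut_bulk].sum(axis=0) / denom for c, g in genos.genotypes.items()}
    f_wt = {c: g[wt_bulk].sum(axis=0) / denom for c, g in genos.genotypes.items()}
    return BulkFrequencies(
        positions=genos.positions,
        f_mut=f_mut,
        f_wt=f_wt,
        causal_chrom=genos.causal_chrom,
        causal_index=genos.causal_index,
        phenotype_counts=(int(wt_idx.size), int(mut_idx.size)),
    )


def _draw_alleles(
    rng: np.random.Generator, n: int, ems_only: bool
) -> tuple[np.ndarray, np.ndarray]:
    if ems_only:
        pick = rng.integers(0, 2, size=n)
        ref = np.where(pick == 0, "G", "C")
        alt = np.where(pick == 0, "A", "T")
        return ref, alt
    ref_i = rng.integers(0, 4, size=n)
    alt_i = (ref_i + rng.integers(1, 4, size=n)) % 4
    return _BASES[ref_i], _BASES[alt_i]


def simulate_reads(
    bulks: BulkFrequencies, cfg: SimConfig, rng: np.random.Generator | None = None
) -> list[BulkVariant]:
    """Sample pooled sequencing reads at every marker.

    Depth per marker and bulk is Poisson(``mean_depth``); the alternate
    count is Binomial(depth, f') where f' folds the true bulk frequency
    with the per-base error rate: ``f' = f(1-e) + (1-f)e``.
    """
    rng = rng if rng is not None else np.random.default_rng(cfg.seed + 2)
    e = cfg.seq_error
    out: list[BulkVariant] = []
    for chrom in cfg.chrom_names:
        pos = bulks.positions[chrom]
        n = pos.size
        ref, alt = _draw_alleles(rng, n, cfg.ems_spectrum)
        if chrom == bulks.causal_chrom:
            ref[bulks.causal_index] = cfg.causal.ref
            alt[bulks.causal_index] = cfg.causal.alt
        depth_mut = rng.poisson(cfg.mean_depth, size=n)
        depth_wt = rng.poisson(cfg.mean_depth, size=n)
        p_mut = bulks.f_mut[chrom] * (1 - e) + (1 - bulks.f_mut[chrom]) * e
        p_wt = bulks.f_wt[chrom] * (1 - e) + (1 - bulks.f_wt[chrom]) * e
        alt_mut = rng.binomial(depth_mut, p_mut)
        alt_wt = rng.binomial(depth_wt, p_wt)
        for i in range(n):
            out.append(
                BulkVariant(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref=str(ref[i]),
                    alt=str(alt[i]),
                    ad_mut=(int(depth_mut[i] - alt_mut[i]), int(alt_mut[i])),
                    ad_wt=(int(depth_wt[i] - alt_wt[i]), int(alt_wt[i])),
                    qual=None,
                )
            )
    return out


def simulate_experiment(
    cfg: SimConfig, out_dir: str | os.PathLike | None = None
) -> SimResult:
    """Run all simulation stages under one seed; optionally write artifacts.

    When ``out_dir`` is given, emits ``bulks.vcf`` (samples MUT, WT),
    ``truth.tsv`` (per-marker true bulk frequencies with the causal row
    flagged) and ``sim_config.json``.
    """
    rng = np.random.default_rng(cfg.seed)
    genos = simulate_f2(cfg, rng)
    bulks = make_bulks(genos, cfg, rng)
    variants = simulate_reads(bulks, cfg, rng)
    result = SimResult(config=cfg, genotypes=genos, bulks=bulks, variants=variants)
    if out_dir is not None:
        out_dir = os.fspath(out_dir)
        os.makedirs(out_dir, exist_ok=True)
        write_bulk_vcf(
            variants,
            os.path.join(out_dir, "bulks.vcf"),
            contig_lengths={c: cfg.chrom_length_bp for c in cfg.chrom_names},
        )
        cfg.to_json(os.path.join(out_dir, "sim_config.json"))
        with open(os.path.join(out_dir, "truth.tsv"), "w") as fh:
            fh.write("chrom\tpos\tf_mut_true\tf_wt_true\tis_causal\n")
            for chrom in cfg.chrom_names:
                for i, p in enumerate(bulks.positions[chrom]):
                    causal = chrom == bulks.causal_chrom and i == bulks.causal_index
                    fh.write(
                        f"{chrom}\t{int(p)}\t{bulks.f_mut[chrom][i]:.6f}\t"
                        f"{bulks.f_wt[chrom][i]:.6f}\t{int(causal)}\n"
                    )
    return result


# ---------------------------------------------------------------------------
# gene fixture


@dataclass
class GeneFixture:
    """Paths and ground truth of the emitted GFF3/FASTA annotation fixture."""

    fasta_path: str
    gff_path: str
    causal_snp: dict  # chrom,pos,ref,alt + expected consequence
    mirror_snp: dict  # the same change on the reverse-complement gene
    gene_id: str
    mirror_gene_id: str


def _random_coding_sequence(
    rng: np.random.Generator, n_codons: int, mutant_codon_index: int
) -> str:
    """ATG ... TGA coding sequence without internal stops; one fixed GGT codon.

    Codon ``mutant_codon_index`` (1-based) is GGT (Gly) so a G>A change at
    its first base yields AGT (Ser).
    """
    codons = ["ATG"]
    all_codons = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]
    sense = [c for c in all_codons if c not in _STOP_CODONS]
    for i in range(2, n_codons):
        if i == mutant_codon_index:
            codons.append("GGT")
        else:
            codons.append(sense[rng.integers(0, len(sense))])
    codons.append("TGA")
    return "".join(codons)


def _write_fasta(path: str, contigs: dict[str, str], width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_gene_fixture(
    out_dir: str | os.PathLike,
    causal: CausalSpec | None = None,
    n_codons: int = 300,
    mutant_codon_index: int = 217,
    exon1_codons: int = 100,
    intron_len: int = 200,
    seed: int = 20240108,
) -> GeneFixture:
    """Write a two-exon gene fixture (GFF3 + FASTA) around the causal SNP.

    The plus-strand gene is laid out so that the first base of codon
    ``mutant_codon_index`` (GGT, in the second exon) falls exactly on
    ``causal.pos``; sequence 5' of the gene is N-padded so fixture
    coordinates line up with the simulated chromosome.  A minus-strand
    mirror of the whole contig is emitted as a second contig for
    strand-symmetry checks, along with a short intergenic flank.
    """
    causal = causal or CausalSpec()
    if not exon1_codons * 3 <= 3 * (mutant_codon_index - 1):
        raise ValueError("mutant codon must lie in the second exon")
    rng = np.random.default_rng(seed)
    cds = _random_coding_sequence(rng, n_codons, mutant_codon_index)
    exon1_len = exon1_codons * 3
    exon1, exon2 = cds[:exon1_len], cds[exon1_len:]
    intron = "GT" + "".join(rng.choice(list("ACGT"), size=intron_len - 4)) + "AG"
    flank = "".join(rng.choice(list("ACGT"), size=300))

    # genomic offset of the mutant codon's first base from the gene start
    codon_cds_off = 3 * (mutant_codon_index - 1)
    genomic_off = exon1_len + len(intron) + (codon_cds_off - exon1_len)
    gene_start = causal.pos - genomic_off
    if gene_start < 1:
        raise ValueError("causal position too close to the contig start for this gene")

    body = exon1 + intron + exon2 + flank
    contig = "N" * (gene_start - 1) + body
    length = len(contig)

    e1 = (gene_start, gene_start + exon1_len - 1)
    e2 = (e1[1] + len(intron) + 1, e1[1] + len(intron) + len(exon2))
    chrom = causal.chrom
    mirror_chrom = f"{chrom}_rc"
    mirror_contig = contig.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]

    def mirror(p: int) -> int:
        return length - p + 1

    me2 = (mirror(e2[1]), mirror(e2[0]))  # mirror gene exon order flips
    me1 = (mirror(e1[1]), mirror(e1[0]))

    gff_lines = ["##gff-version 3\n"]

    def gene_block(gid: str, seqid: str, strand: str, exons: list[tuple[int, int]]) -> None:
        start = min(s for s, _ in exons)
        end = max(e for _, e in exons)
        gff_lines.append(
            f"{seqid}\tedmap\tgene\t{start}\t{end}\t.\t{strand}\t.\tID={gid}\n"
        )
        mid = f"{gid}.1"
        gff_lines.append(
            f"{seqid}\tedmap\tmRNA\t{start}\t{end}\t.\t{strand}\t.\tID={mid};Parent={gid}\n"
        )
        ordered = sorted(exons)
        # phases in translation order
        trans_order = ordered if strand == "+" else ordered[::-1]
        phases = {}
        cum = 0
        for iv in trans_order:
            phases[iv] = (3 - cum % 3) % 3
            cum += iv[1] - iv[0] + 1
        for i, (s, e) in enumerate(ordered, 1):
            gff_lines.append(
                f"{seqid}\tedmap\texon\t{s}\t{e}\t.\t{strand}\t.\t"
                f"ID={mid}.exon{i};Parent={mid}\n"
            )
            gff_lines.append(
                f"{seqid}\tedmap\tCDS\t{s}\t{e}\t.\t{strand}\t{phases[(s, e)]}\t"
                f"ID={mid}.cds{i};Parent={mid}\n"
            )

    gene_block("geneA", chrom, "+", [e1, e2])
    gene_block("geneB", mirror_chrom, "-", [me1, me2])

    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    fasta_path = os.path.join(out_dir, "gene_fixture.fa")
    gff_path = os.path.join(out_dir, "gene_fixture.gff3")
    _write_fasta(fasta_path, {chrom: contig, mirror_chrom: mirror_contig})
    with open(gff_path, "w") as fh:
        fh.writelines(gff_lines)

    expected = f"G{mutant_codon_index}S"
    causal_snp = {
        "chrom": chrom,
        "pos": causal.pos,
        "ref": causal.ref,
        "alt": causal.alt,
        "effect": "missense",
        "short_form": expected,
    }
    mirror_snp = {
        "chrom": mirror_chrom,
        "pos": mirror(causal.pos),
        "ref": "C",
        "alt": "T",
        "effect": "missense",
        "short_form": expected,
    }
    return GeneFixture(
        fasta_path=fasta_path,
        gff_path=gff_path,
        causal_snp=causal_snp,
        mirror_snp=mirror_snp,
        gene_id="geneA",
        mirror_gene_id="geneB",
    )
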