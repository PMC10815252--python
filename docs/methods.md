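# Methods

## Experimental design being modelled

The package targets MutMap-style bulked-segregant mapping of an induced
mutation. A mutant line carrying a single causal change (EMS mutagenesis,
hence a G:C→A:T transition) is crossed to its wild-type progenitor; the F1
is selfed; the F2 segregates the phenotype (3:1 for a dominant mutation).
Two bulks of F2 plants — selected purely by phenotype — are sequenced as
pools, and every SNP distinguishing the parental genomes reports the local
ratio of mutant-line to wild-type-line chromosomes in each bulk. Near the
causal locus, phenotype selection distorts that ratio; elsewhere it stays
near 1:1.

Under dominance, the mutant-phenotype class is 1/3 homozygous and 2/3
heterozygous carriers, so the expected causal-allele frequency in the
mutant bulk is (1/3)·1 + (2/3)·(1/2) = 2/3, while the wild-phenotype bulk
is homozygous reference (frequency exactly 0 when phenotyping is
error-free). The expected ED at the causal SNP is therefore
√2·(2/3) ≈ 0.9428. Under recessivity the mutant bulk fixes the allele
(frequency 1, ED √2).

## Association scan

* **ED statistic.** Computed over both allele classes and algebraically
  equal to √2·|f_mut − f_wt| for a biallelic site. Frequencies are
  alt_depth / total_depth per bulk; zero-depth sites must be filtered
  first (default: total depth ≥ 10 in each bulk, QUAL ≥ 30, biallelic
  SNVs only).
* **Power transform.** ED is raised to k = 5 before thresholding, the usual
  choice in ED-based BSA-seq work; it sharpens the peak-to-background
  contrast but, being monotone, does not change which sites rank highest.
* **Threshold.** The empirical 99.5% quantile (linear interpolation between
  order statistics, the numpy default rule, pinned by an independent
  sort-and-interpolate oracle in the tests) of the powered ED, computed
  genome-wide across all retained sites. A per-chromosome option exists.
* **Regions.** Above-threshold sites (strictly greater than the threshold)
  on one chromosome are joined greedily while consecutive gaps are
  ≤ 1 Mb; a cluster is reported when it contains ≥ 10 above-threshold
  sites, spanning its first to last above-threshold site. Region
  boundaries are not extended beyond those markers.
* **Smoothing.** Off by default; an optional physical-distance moving
  average of the powered ED is available (`smoothing="moving_average"`,
  `window_bp`).

## Candidate-SNP selection

Inside candidate regions, SNPs are kept when the wild-bulk frequency is
≤ 0.1 and the mutant-bulk frequency falls in [0.4, 0.85] (dominant mode;
[0.9, 1.0] in recessive mode), with ≥ 10× depth per bulk. The windows are
deliberately wide: at 40× and 30-plant bulks the sampling standard
deviation of the causal f_mut is ≈ 0.086, and the dominant window keeps
the causal SNP in ≥ 95% of replicates. Survivors are intersected with
damaging predicted effects (missense, nonsense, start/stop loss, splice
site) and ranked by powered ED, ties broken by position. An optional
EMS-spectrum filter (G→A / C→T only) exists but is off by default.

## Effect annotation

A minimal codon-level annotator for single-base substitutions. The spliced
CDS is rebuilt from GFF3 CDS intervals (reverse-complemented on the minus
strand), the affected codon is located by its CDS offset, and ref/alt
codons are translated with the standard nuclear code (Biopython). Classes:
synonymous / missense / nonsense / start_lost / stop_lost inside CDS;
splice_site within 2 bp of an exon–intron boundary on the intron side
(GT-AG rule); intronic within a gene otherwise; intergenic outside all
genes. Design choices:

* Exonic but non-CDS (UTR) positions are lumped with `intronic` — the
  effect vocabulary has no UTR class and the fixtures model CDS-only exons.
* With multiple overlapping transcripts, the single most severe effect is
  reported (nonsense > start_lost > stop_lost > missense > splice_site >
  synonymous > intronic > intergenic).
* The REF allele is checked against the genome base; an `N` in the
  assembly (unassembled or masked sequence) skips the check, and the batch
  wrapper classifies positions on absent contigs or beyond contig ends as
  intergenic. Codons containing ambiguity codes annotate as `unknown`.
* Residues count the initiator Met as 1, so Gly217→Ser prints `G217S`.
* Equivalence with a brute-force oracle (rebuild the whole protein for ref
  and alt, diff) is asserted on 1,000 random SNPs over both strands.

## Forward simulator

* **Meiosis.** Haldane model: crossover count per chromosome is
  Poisson(length_Mb · cM_per_Mb / 100) with uniform breakpoints and no
  interference. Default 3 cM/Mb over 50 Mb chromosomes (≈ 150 cM each),
  a cereal-scale genetic map.
* **Markers.** 1,000 evenly spaced markers per chromosome, every one
  informative (the two parental lines carry fixed alternate alleles),
  plus the causal SNP inserted at chr1:885,631 — the coordinate of the
  mapped G→A change in the sorghum study the defaults emulate.
* **Bulks.** 30 plants sampled without replacement per phenotype class
  from a 412-plant F2; misclassification rate 0 by default (phenotyping at
  the shooting stage is unambiguous), configurable.
* **Reads.** Depth per marker and bulk ~ Poisson(40); alternate counts ~
  Binomial(depth, f(1−e) + (1−f)e) with per-base error e = 0.001. No
  read-level artifacts (duplicates, mapping bias, indel noise) are
  modelled, so passing tests demonstrate statistical behaviour of the
  method, not robustness to alignment pathologies.
* **Determinism.** One `numpy` Generator seeded from `SimConfig.seed`
  drives all stages; emitted VCF/TSV files are byte-identical across runs
  with the same config.
* **Gene fixture.** A two-exon plus-strand gene is written so that codon
  217 (GGT, Gly) starts exactly at the causal position in the second exon;
  the contig is N-padded 5' of the gene so fixture coordinates match the
  simulated chromosome. A full reverse-complement mirror contig carries
  the same gene on the minus strand for strand-symmetry checks.

## Known limitation: desk-scale region calling

The genome-wide empirical quantile is *fixed-count*: exactly ~0.5% of
sites exceed the 99.5% quantile regardless of how strong the causal signal
is. At production scale (millions of SNPs) that is ~10,000 sites and
clusters of ≥ 10 form easily inside linked regions. At the simulator's
default desk scale (2 × 1,000 markers) only ~10 sites genome-wide can be
above threshold, so the ≥ 10-site rule demands that essentially *every*
above-threshold site fall within one chain of ≤ 1 Mb gaps. Independent
read-sampling noise at 40× (σ_f ≈ 0.075) is comparable to the
linkage-decay signal between adjacent 50-kb markers, so the top sites
scatter across the ±4 Mb linkage valley and the chain often breaks: a
region containing the causal SNP is called in roughly a third of
replicates under the default configuration (the rate rises steeply with
depth or with the merge gap). The mean causal-marker ED (≈ 0.94) and the
zero wild-bulk causal frequency are unaffected. For small marker panels,
raising `merge_gap_bp`, lowering `min_sites`, or enabling smoothing are
the appropriate knobs; the defaults are kept at the standard
production-scale values.

## Packaged reference tables

Two small tables from the sorghum lobed-leaf study ship with the package:
the 22 candidate intervals (start/end in Mb with per-interval gene and
transcript counts; they sum to 8.996802 Mb, 960 genes, 1,328 transcripts)
and the observed F2 segregation counts (118 wild type : 294 mutant).
For the segregation test both the plain Pearson statistic (2.9126) and the
Yates continuity-corrected statistic (2.7217) are reported: the statistic
printed in the source study (2.63) matches neither formula exactly and is
not reproduced here.

## Numerical conventions

* Coordinates: 1-based inclusive for VCF/GFF3 and regions; BED exports are
  0-based half-open.
* Quantile: linear interpolation between order statistics.
* "Above threshold" is strict (>); with a continuous statistic, ties have
  measure zero.
* Ranking ties in the candidate table break by (chrom, pos) with a stable
  sort.
* Empty inputs: filtering an empty list returns an empty list; a quantile
  of no values and an all-zero segregation table are errors.
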