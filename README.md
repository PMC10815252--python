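# edmap

Euclidean-distance bulked-segregant mapping of induced mutations from
pooled F2 sequencing.

`edmap` is for geneticists running MutMap-style experiments: a mutant
(here, an EMS-induced dominant sorghum leaf-morphology mutant) is crossed
to its wild-type progenitor, the F1 is selfed, and two bulks of F2 plants —
one per phenotype class — are whole-genome sequenced as pools. The package
takes the called variants (a two-sample VCF with allelic depths), locates
the genomic region linked to the phenotype, and narrows it to candidate
causal SNPs.

## The statistic

At each biallelic SNP with alternate-allele frequencies `f_mut` and `f_wt`
in the two bulks, the Euclidean distance over both allele classes is

```
ED = sqrt((f_mut − f_wt)² + ((1 − f_mut) − (1 − f_wt))²) = √2 · |f_mut − f_wt|
```

ED is ~0 at loci unlinked to the phenotype and approaches √2 at fully
divergent loci. Raising it to a power *k* (default 5) suppresses the
sampling-noise background. Sites whose powered ED exceeds the genome-wide
99.5% empirical quantile are clustered into candidate regions (gap ≤ 1 Mb,
at least 10 above-threshold sites). For a *dominant* causal SNP the
mutant-phenotype bulk is a 1:2 mix of homozygous and heterozygous carriers,
so its expected frequency pattern is `f_mut ≈ 2/3`, `f_wt = 0` — the
zygosity filter keeps SNPs matching that pattern, and a built-in
codon-level annotator (GFF3 + FASTA) restricts candidates to damaging
consequences (missense, nonsense, start/stop loss, splice site), ranked by
powered ED. A chi-square module tests phenotype segregation against
Mendelian ratios such as 3:1.

A seeded forward simulator of the whole design (Haldane meiosis, phenotype
selection, pooled Poisson/binomial read sampling) generates VCF/GFF3/FASTA
inputs with known ground truth.

## Worked example

Simulate the default experiment (412 F2 plants, bulks of 30, 40× pooled
depth, 2 chromosomes × 1,000 markers, causal G→A SNP at chr1:885,631) and
run the full pipeline:

```
$ edmap all --seed 0 --out-dir demo
{"n_regions": 1, "n_candidates": 1, "causal_in_region": true, "causal_ranked_first": true}

$ head -2 demo/candidates.tsv
region	chrom	pos	ref	alt	effect	short_form	ed_k
chr1:275000-2225000	chr1	885631	G	A	missense	G217S	0.40354422266182205
```

One candidate region is called on chromosome 1 and the single ranked
candidate is the simulated causal SNP: a G→A missense change converting
glycine 217 to serine (`G217S`) in the fixture gene's second exon. The
output directory also holds the scan table, region BED, Manhattan plot and
the simulation truth table.

The packaged study tables can be re-summarized directly:

```
$ edmap table-check
regions	22	total_size_mb	8.996802	genes	960	transcripts	1328
segregation	observed	118	294	expected	103	309	chi2_pearson	2.9126	chi2_yates	2.7217

$ edmap segtest --n-wt 118 --n-mut 294
obs_wt	obs_mut	exp_wt	exp_mut	chi2_pearson	chi2_yates	p_pearson	p_yates
118	294	103	309	2.9126	2.7217	0.08789	0.09899
```

The 22 published candidate intervals sum to 8.996802 Mb containing 960
genes (1,328 transcripts), and the observed 294:118 phenotype split is
consistent with 3:1 (p ≈ 0.09), supporting a single dominant mutation.

Other subcommands: `simulate`, `scan`, `annotate`, `filter`, `segtest`;
`edmap --show-config` prints every default parameter.

## Layout

- `edmap.variant_io` — two-bulk VCF reading/writing, depth/quality filters
- `edmap.ed_scan` — ED statistic, power transform, quantile threshold, region calling, Manhattan plot
- `edmap.effect_annotator` — codon-level SNP consequences from GFF3 + FASTA
- `edmap.candidate_filter` — zygosity windows and effect-based ranking
- `edmap.segregation` — Mendelian chi-square goodness of fit
- `edmap.simulate` — forward simulator and gene-fixture generator
- `edmap.pipeline` / `edmap.cli` — orchestration and the `edmap` command

See `docs/methods.md` for the model details, parameter choices and known
limitations.
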