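# Methods

This note documents the statistical model behind `cnvselscan`, the
conventions and numerical choices the implementation fixes, what the
synthetic-data generator does and does not emulate, and known limitations.

## Data model

The unit of analysis is a biallelic structural variant — in the target
application a deletion CNV — genotyped across a diploid cohort split into
two groups, HL (high litter size) and LL (low litter size), 15 + 15
individuals in the reference design. Genotypes are alt-allele dosages
{0, 1, 2} with an explicit missing state; half-missing VCF calls (`./0`)
are treated as missing, which biases no frequency estimate. Coordinates
are 1-based inclusive throughout (VCF/GFF3 native); BED input is converted
at the boundary. For deletions, INFO/END is defined as POS + |SVLEN| − 1
when absent; when both are present and disagree by more than 1 bp, END
wins (Manta-style VCFs treat END as authoritative). The VCF writer formats
records directly because htslib-based writers now re-derive END from SVLEN
under the newer END = POS + |SVLEN| convention, which is off by one
against this dialect.

## Population merging

Two calls duplicate one another when they share chromosome and SV type,
their reciprocal overlap min(shared/len(a), shared/len(b)) reaches the
type threshold (0.5 for DEL, 0.9 for INS/INV/DUP, both inclusive), and
their genotype concordance — the fraction of samples non-missing in both
with identical genotype, defined as 1 when no sample is comparable — is at
least 0.95. Clusters are single-linkage (the convention of SV-merging
tools such as SURVIVOR), so transitive chains can join pairs that are
individually sub-threshold; this is intended behaviour and is exercised in
the tests. Insertions have near-zero reference span, so they use
breakpoint distance ≤ 100 bp plus length ratio ≥ 0.9 instead of reciprocal
overlap. The cluster representative takes the component-wise median
breakpoints (lower of the two middles for even counts) and the per-sample
majority genotype over non-missing member calls, falling back to missing
on ties — chosen for robustness and determinism; the surviving record is
otherwise arbitrary. Merging well-separated callsets is idempotent and
order-independent; idempotence is not a mathematical guarantee for
arbitrarily dense inputs, since medians of two clusters can themselves
become mergeable.

## Quality control

Filters run in a fixed order — length, excess heterozygosity, missingness,
minor allele frequency — and a record is attributed to the first filter it
fails, so the per-filter counts depend on the order but the surviving set
does not (asserted in tests). All comparisons are exactly as written:
|SVLEN| ≤ 10,000,000; excess-het p ≥ 0.05; F_MISSING ≤ 0.2 (a record at
exactly 0.2 survives); MAF strictly > 0 (a monomorphic record is removed).
The excess-het statistic is the one-sided exact Hardy–Weinberg p-value for
heterozygote excess, P(het ≥ observed) under the conditional distribution
of heterozygote counts given the allele counts (the Wigginton–Cutler–
Abecasis enumeration, evaluated in log space with a log-sum normalisation;
exact to ~1e-15 against rational-arithmetic enumeration). It is computed
over the pooled cohort, matching the standard meaning of the ExcHet tag in
variant toolchains, which apply it before any group split; a plain (not
mid-) p-value is used. MAF and missingness are recomputed from genotypes
rather than read from INFO, since merging invalidates INFO summaries.
A record with every genotype missing cannot show het excess and falls
through to the missingness filter (or, under relaxed thresholds, to its
own `maf_undefined` accounting bucket).

## Selection scan

Per site, the two-population Weir–Cockerham (1984) variance components
a (among populations), b (among individuals within populations) and
c (within individuals) are computed from the per-group sample sizes,
allele frequencies and observed heterozygosities. Sites are skipped when a
group has no called genotype, when the mean sample size is ≤ 1, or when
a + b + c = 0 (monomorphic). The windowed estimate is the weighted ratio
of sums Σa / Σ(a+b+c) over the sites whose POS falls in the window — the
estimator VCFtools reports for windowed scans — not the mean of per-site
ratios, which over-weights low-information sites. Negative window values
are retained in the output (the candidate filter consumes them) but can
never rank in the upper tail.

Nucleotide diversity per site is the unbiased mean pairwise difference
2p(1−p)·n/(n−1) over n non-missing alleles, computed separately per
group; the window value divides the summed site diversities by the
window's genomic span (clipped windows by their actual span), making the
HL/LL ratio span-invariant. The contrast is log₂(π_HL/π_LL), defined only
when both diversities are positive; windows where either is zero are
excluded from ranking and counted, since no finite value exists and an
infinite pseudo-value would dominate any quantile.

Windows are 100 kb advanced by 10 kb, starting at position 1 and clipped
at the chromosome end. A variant belongs to a window iff its start
breakpoint lies inside — the per-site convention of windowed popgen tools —
so windows are independent of variant length and a spanning CNV is not
multiply counted.

Candidate windows must lie in the top 1% of windowed F_ST (upper tail,
fixed) *and* in the extreme 1% of the log₂ π-ratio. The ratio tail
defaults to both tails at 0.5% each, since a sweep in either group is a
signal; when the direction of interest is known (as for a planted or
hypothesised HL sweep) the scan is configured one-tailed. Quantiles are
empirical (linear interpolation) over defined-statistic windows only, and
every window tied with the threshold value is included — deterministic,
and never fewer windows than the exact count. Selected windows map to the
CNVs whose POS they contain; a variant in several overlapping selected
windows is one locus carrying all supporting windows. The final filter
keeps loci that overlap at least one gene body (≥ 1 bp, no flank) and
whose maximum supporting-window F_ST is non-negative — zero is retained
under a strict reading of "negative".

## Annotation

Feature categories follow the precedence ladder of common variant
annotators: exonic > splicing > UTR5 > UTR3 > ncRNA_exonic >
ncRNA_intronic > intronic > upstream/downstream (both at once merge into
a combined category) > intergenic, with a 1 kb strand-aware flank — the
documented defaults of the named annotator class, since settings beyond
the tool name are not standardised. A splicing call touches a 2 bp splice
site (the first or last two bases of a gap between exon-like features)
without touching an exon. A CNV overlapping several genes takes the
highest-precedence category across them. Gene *assignment* for the
candidate filter uses gene-body overlap only, reading "not enriched for
genes" as zero gene-body overlap.

## Cohort statistics

Per-group CNV frequencies are allele frequencies over non-missing alleles
(what PLINK computes), binned into ten intervals [0, 0.1), …, [0.9, 1.0].
Each bin is compared between groups with a two-sided Fisher exact test on
the (in-bin vs out-of-bin) × (HL vs LL) table; a bin empty in both groups
is p = 1 by convention. The per-chromosome contrast is operationalised as
a 2×2 chi-square of presence counts (a variant is present in a group when
its alt-allele count there is ≥ 1) on versus off the chromosome, by group,
with Yates continuity correction (the default of mainstream stacks,
switchable off); the Bonferroni multiplier is the number of chromosomes
actually tested. PCA uses a VanRaden genetic relationship matrix:
dosages mean-imputed per variant, centred at 2p and scaled by
√(2p(1−p)), monomorphic variants dropped, G = ZZᵀ/m; coordinates are
eigenvectors scaled by √eigenvalue, with each component's sign fixed so
its largest-magnitude loading is positive (reproducibility only).

## Synthetic data

The generator emulates a genotyped, already-merged deletion callset: sites
placed uniformly without overlap (lengths log-uniform, 1–100 kb by
default), ancestral frequencies Beta(0.8, 0.8) truncated to [0.05, 0.95]
so the MAF filter is exercised without dominating, group frequencies from
the Balding–Nichols model at a chosen F, genotypes binomial(2, p) within
groups (exact Hardy–Weinberg sampling), and genotype-wise i.i.d.
missingness. A planted sweep region overrides the group frequencies of
every site inside it. Fragmentation into per-individual callsets emits one
single-sample record per carrier, translates breakpoints by a uniform
offset within ± jitter (capped at half the span), and drops records at a
dropout rate. Toy annotations place equal-length non-overlapping gene
models (UTRs, exons, introns; a fraction as ncRNA genes) covering a
configurable genome fraction; the CLI default density is one gene per
~150 kb, roughly mammalian.

Deliberately not modelled: linkage disequilibrium between CNVs (each site
is independent, so a planted sweep has no hitchhiking shoulder), caller
error modes beyond breakpoint jitter and dropout, pedigree structure,
non-deletion SV types (available behind a flag only to exercise the 90%
merge threshold), and informative missingness. Passing tests therefore
demonstrate correctness of the estimators and decision rules, not
robustness to the correlated noise of real short-read callsets.

## Problem sizes and validation conditions

The validation suite uses: 500 random sites for oracle agreement; 5,000
sites at 15 + 15 samples for F_ST calibration at targets {0.01, 0.05,
0.15, 0.3} (tolerance ± 0.03, five replicates each); a 10 Mb genome with
5,000 sites, neutral F 0.03 and one 200 kb sweep at frequencies 0.99/0.05
for scan recovery over 20 replicates; exhaustive enumeration up to 20
diploid samples for the excess-het test and up to total count 40 (plus a
seeded sample of larger margin-≤ 40 tables) for Fisher agreement; and
1,000 sites at F 0.2 over 20 replicates for PCA separation. The sweep uses
near-fixation (0.99) rather than exact fixation because a sweep fixed in
one group and absent in the other leaves *both* groups monomorphic across
the region, making the diversity ratio 0/0 — undefined under the exclusion
policy above — and erasing the very contrast the scan ranks on; real
sweeps retain residual diversity. Sweep-window recovery is reported
against the windows fully contained in the sweep region. Note a structural
ceiling on that recovery: a 200 kb sweep fully contains 10–11 windows of
the 100 kb/10 kb grid while the top 1% of a 10 Mb genome's ~1,000 ranked
windows holds ~10 slots, and neighbouring windows share ~90% of their
sites, so the tail cut falls near-randomly among 11–12 near-tied
windows in each statistic; the measured intersection recovery plateaus
around 0.85 with precision 1.0.

## Limitations

- The diversity statistics operate on the CNV genotype matrix itself, not
  on accompanying SNP data; absolute π values are per-CNV-site, not
  per-nucleotide in the sequence sense.
- Quantile thresholds on ~1,000 windows are coarse; candidate counts step
  discretely with the number of ranked windows.
- The merge stage assumes one shared sample panel; cross-cohort merging
  and BND/translocation records are out of scope.
- Bonferroni is the only multiplicity correction offered for the
  chromosome tests, matching the target workflow.
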