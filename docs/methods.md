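# Methods

## Pooled SNP calling

The caller operates on per-site nucleotide counts from a pooled
alignment (native TSV dialect `contig pos ref A C G T indel_count`, or
a sync-style mpileup-derived count table). Counts from ambiguous bases
contribute to depth but are never candidate alleles.

A site yields a call when

* depth ≥ `min_cov` (default 30), and
* the second-most-frequent base count ≥ `min_count` (default 6).

`min_count` applies to the single second-most-frequent base, not the
sum of non-reference bases; this is standard pooled-caller practice and
makes the detectability arithmetic exact: the smallest copy class k out
of n = 20 chromosomes detectable in expectation at depth d is
⌈`min_count`·n/d⌉ — 4/20 at depth 30, singletons from depth 120.
Allele ranking breaks count ties in favour of the reference base, then
alphabetically, so calls are deterministic. A third allele reaching
`min_count` marks the site `multiallelic` and suppresses the call
(rare under a 2×10⁻³ error model; the reason log preserves such sites
for inspection). The minor-allele copy class is round-half-up of
p̂·n, clamped to 1..n−1: a called SNP is segregating by definition, so
an estimated class of 0 promotes to 1.

Two masks run before the thresholds, in this order: indel proximity
(± `indel_window` = 5 bp around any site with indel evidence — no
radius is canonical, 5 bp is a common exclusion window) and excess
coverage (above the per-contig empirical `max_cov_quantile` = 0.98 —
enrichment and PCR bias inflate depth locally and no absolute cutoff
generalises across runs). Both defaults are configurable.

Reason codes for no-calls: `low_coverage`, `monomorphic`, `low_count`,
`multiallelic`, `indel_proximal`, `excess_coverage` (the first
applicable in that evaluation order is recorded).

Call-set intersection matches on (contig, pos, minor allele) by
default (position-only is available); the shared set keeps the first
argument's frequency estimates, since one canonical p̂ is needed
downstream. Validation against a truth set counts TP/FP/FN inside a
stated region; fp_rate = FP/(TP+FP) and fn_rate = FN/(TP+FN), each
undefined (None) on a zero denominator. Fixed differences to the
reference — positions where the pool is effectively monomorphic for a
non-reference base — are not within-population SNPs and are removed by
`filter_fixed_differences`.

## Diversity statistics

Per-site diversity uses the pooled estimator 2·p̂·(1−p̂)·n/(n−1) on
the estimated minor-allele frequency (correction removable by flag).
Per-gene π divides the sum over all CDS SNPs by the full CDS length
(all sites, not only polymorphic ones). πN and πS divide the sums over
nonsynonymous/synonymous SNPs by Nei–Gojobori site totals: each codon
position contributes a fraction of a synonymous site equal to the
fraction of its three possible changes that preserve the amino acid.
Mutations creating stops count as nonsynonymous and reference stop
codons are excluded from totals (the standard Nei–Gojobori
convention); each sense codon therefore contributes exactly 3 sites,
and N+S equals the CDS length for stop-free frames. πN/πS is reported
as 0 when πN = 0 with πS > 0 and as undefined (NaN in reports) when
πS = 0; rounding to report precision happens only at the output layer.

Effect classification substitutes the single alternate base into the
reference codon (minus-strand genes on the reverse complement). When
two SNPs share a codon each is classified against the reference
background with a warning — at the SNP densities this pipeline targets
(tens of SNPs over kb-scale genes) codon co-occupancy is rare, and
pathway averaging would add model weight without data to support it.
Ts/Tv counts A↔G and C↔T as transitions over reference→alternate
pairs, undefined when no transversions exist.

## Folded site-frequency spectrum

SNPs are binned by minor-allele copy class k₀ = clamp(round(p̂·n), 1,
n−1) folded to min(k₀, n−k₀) ∈ {1..n/2}; rounding is half-up (ties at
.5 go to the larger class) since no convention is canonical for
converting pooled frequencies to copy classes. Relative spectra
(counts normalised to 1) are the comparison currency; spectra are
compared by Pearson correlation over the n/2 classes, undefined for
empty or zero-variance spectra.

## Heterozygosity-decay model

Heterozygosity H is the probability that two sampled alleles differ;
for a panel of loci it is operationalised as the expected proportion
of polymorphic loci. The propagation history is: a founder step — a
single selfed founder halves H, a cross among founders with selfing
rate s retains f = 1 − 0.5·s of it — followed by rounds of random
mating among 2N chromosomes, each retaining (1 − 1/2N).

`t_total` counts the founder step as the first of the total rounds of
multiplication, so inversion uses H₀ = H_sample/[f·(1 − 1/2N)^(t_total−1)].
With H_sample = 13/220 and t_total = 10 this yields H₀ = 0.17/0.21
(s = 1, 2N = 24/16) and 0.12/0.14 (s = 0.5); reading all ten rounds as
random-mating rounds instead would give ≈ 0.18/0.23 and is rejected
because it is inconsistent with the founder step being part of the
multiplication history. An implied H₀ > 1 is returned with a
feasibility flag rather than an error. Reported H₀ is rounded to two
decimals only at the reporting layer.

The Monte-Carlo validator initialises each locus as polymorphic with
probability 2·H₀ at founder frequency p = 1/2 — so the expected
heterozygosity 2p(1−p) starts exactly at H₀ (this requires H₀ ≤ 0.5) —
applies the founder factor as a deterministic multiplier of expected
heterozygosity (the model's founder generation is an expectation
recursion, not a mating event), and then runs t_total − 1
Binomial(2N, p) Wright–Fisher rounds. Binomial resampling removes
exactly 1/2N of expected heterozygosity per round, so the simulated
mean tracks the analytic recursion at every generation; tests hold it
to within a few Monte-Carlo standard errors, and the forward
simulation from an inverted H₀ recovers the observed H_sample.

## Synthetic data generator

The generator emulates the study design the pipeline assumes: 220
target genes, a pool of 10 diploid plants (20 chromosomes, equal DNA),
deep exon-targeted coverage, and a small residual error rate after
stringent quality trimming. Defaults: mean coverage 346× with
negative-binomial dispersion 5 — chosen so the first-quartile/median
coverage ratio (≈ 0.72) matches deep enrichment data; no distributional
form is canonical for capture depth, and the negative binomial is the
usual overdispersed choice — 13/220 polymorphic genes, ~18 segregating
sites per polymorphic gene, and ε = 2×10⁻³ uniform miscalls (a
placeholder for the post-Q30-trimming error rate, which such studies do
not report; configurable).

References are random sense-codon ORFs (ATG start, no stops), half
split by a GT..AG intron and ~30 % on the minus strand, one contig per
gene. Segregating sites sit at distinct uniform CDS positions with
uniform non-reference bases; effect labels come from codon
substitution. All sites of a gene share one copy number: a selfing,
bottlenecked population descends from at most two ancestral haplotypes
per locus, so linked variants travel at the same frequency — which is
also what produces the lumpy per-gene spectra seen in real pools.
Without a propagation scenario, a gene is polymorphic with probability
`polymorphic_fraction` and its copy number is uniform on 1..n−1. With
a scenario, gene ancestry is simulated forward: polymorphic at
founding with probability 2·H₀ (frequency 1/2), founder loss applied
as a thinning by f, t_total − 1 Wright–Fisher rounds, and the gene
deemed polymorphism-carrying with probability 2p(1−p) at its final
frequency — the literal two-sampled-alleles-differ definition — which
makes the expected fraction of segregating genes equal the analytic
decay exactly; the copy number is then Binomial(n, p) conditioned on
1..n−1. (Declaring segregation directly from the 20-chromosome sample
would decay more slowly than 2p(1−p) and break that correspondence;
the two notions of "heterozygosity" genuinely differ.)

Pileup counts: depth ~ NegBin(mean, dispersion) per site; each read is
alternate with probability k/n at truth sites, then miscalled to a
uniform other base with probability ε. Sites are independent — no
statistic in scope uses linkage disequilibrium. Not emulated: read-level
artefacts (FASTQ, mapping error, duplicates), probe-affinity bias and
copy-number variation, indel *errors* (indel evidence can be injected
at a chosen rate purely to exercise the caller's mask), and
multiallelic truth (the caller must still survive multiallelic counts
arising from miscalls). Passing tests on these pools therefore
demonstrate the statistical behaviour of the count rules under the
stated depth/error model, not robustness to alignment artefacts.

## Problem sizes and numerics

Tests exercise the full chain on 60 genes × 1.2 kb (≈ 72 k sites,
~430 truth SNPs) at the default depth/error settings, which gives
sub-percent standard errors on recall and false-positive rates;
Monte-Carlo drift checks use 220 loci × 2000–3000 replicates. The
acceptance script uses 220 loci × 3000 replicates for the forward
simulation. All randomness flows through a single seeded numpy
Generator per run; outputs are bit-reproducible for a fixed seed.
Degenerate inputs resolve to flags, not numbers: empty spectra, πS = 0
ratios, zero-variance correlations and zero validation denominators
are all reported as undefined rather than silently zero or infinite.

## Known limitations

* The caller has no genotype-likelihood model; it is a count-threshold
  caller by design, matching the rules it exists to study.
* πN/πS per gene is undefined whenever no synonymous diversity exists —
  frequent in sparse data; downstream consumers must handle NaN.
* The drift model has no mutation, migration or selection; it is only
  meant for few-generation propagation histories.
* The generator's independence and shared-copy-number assumptions make
  per-gene SFS shapes degenerate (one class per gene); the global SFS
  across genes is the meaningful testing target.
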