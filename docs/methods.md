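# Methods

This note documents the statistical procedures, the synthetic-data model, the
parameters that matter, and the numerical choices behind `polyat`.

## Composition statistics

**[AT] value.** For sequences, (nA+nT)/(nA+nC+nG+nT); N bases are counted and
reported but excluded from every fraction. For polymorphic sites, each
accession contributes weight 1 to its homozygous base and 0.5 to each of
ref/alt when heterozygous; missing calls drop out of both numerator and
denominator. Heterozygote dosage is fixed at exactly 0.5 (an allele-counting
rule, not a likelihood-based dosage). Soft-masked (lowercase) reference bases
are counted as their base, so sequence totals match whole-genome counts.

**PR2 deviation.** dAT = [A]−[T] and dCG = [C]−[G], signed, on single-strand
counts. Under a strand-symmetric substitution process both are 0 in
expectation; the test suite checks |dAT|, |dCG| < 0.005 on a 5-Mb simulated
genome (the i.i.d. binomial bound at that length is ~100x smaller).

**Shuffling test.** The significance of an [AT] difference between two
sequence pools is assessed by a multinomial bootstrap: n_iter (default 100)
replicates of sample_size base labels drawn i.i.d. from each pool's
composition, followed by an equal-variance two-sample t test on the replicate
[AT] values (Welch by flag). The resampling unit is the single base; draws
are with replacement. Sample sizes are capped at 1e8 — whole-genome-scale
shuffles carry no additional information for a 100-replicate t test, only
runtime. Deterministic under a seed.

**Duncan's multiple range test.** One-way ANOVA MSE; groups sorted by mean; a
pair spanning p ordered means differs when its mean difference exceeds
R_p = q(1−α_p; p, df)·sqrt(MSE/n_h), with the Duncan protection level
α_p = 1−(1−α)^(p−1) and n_h the harmonic-mean group size; the step-down
procedure does not test ranges inside an accepted span, and letters are the
maximal non-significant spans. The test is **F-protected**: when the omnibus
F test is not significant at α, all groups share one letter. Unprotected
Duncan is notoriously liberal (familywise error ≈ 1−(1−α)^(k−1)); the
protected variant keeps the null single-letter rate at ≥ 1−α, which is what
the calibration tests assert, and matches common agronomic practice. With
zero MSE and unequal means, all pairs are declared different.

**Windows.** 2-Mb windows sliding by 1 Mb (configurable). A window's value is
the group mean of per-accession [AT] values over the SNPs inside it (the
per-accession rule extended to windows; pooling alleles across accessions is
not used). Windows with fewer than `min_sites` = 10 SNPs are flagged missing;
trailing partial windows are kept subject to the same minimum. The
wild-vs-domesticated window difference Δ[AT] is the absolute difference of
fractions (boundaries 0 and 0.1 live on this scale); a relative
(percent-change) column is also emitted because per-chromosome increases are
sometimes quoted that way. Strata (sweeps, recombination zones) with fewer
than `min_sites` SNPs are skipped with a log message rather than compared.

## Annotation

The classifier assigns exactly one of seven classes per SNP. Inside CDS the
ref and alt codons are translated (strand-aware, standard nuclear code):
same amino acid → synonymous, different → missense, start-loss/stop-gain/
stop-loss → other_genic (no extra classes for splice effects; introns are
not modelled at the donor/acceptor level). Exonic non-CDS positions are UTR;
within a transcript but no exon → intronic; within `proximal_bp` = 5000 of a
gene span (the named effect-annotation tool's default; configurable) →
gene_proximal; else intergenic. Across transcripts the most severe effect
wins, ordered missense > synonymous > other_genic > utr > intronic.
Transcripts whose CDS length is not a multiple of 3 are skipped with a
warning. If the VCF ref allele disagrees with the reference genome base, the
genome supplies the codon context and both alleles are substituted into it.
The genic/non-genic merge pools intergenic + gene_proximal as non-genic and
the other five classes as genic. Equal-size comparisons use seeded uniform
subsampling without replacement.

## Mutation spectrum

Transition types are unordered ref/alt pairs (6 values). Motifs are the
reference-strand flanking bases at pos±1 around the SNP; chromosome-end and
N-flank sites are unusable for motifs (excluded from motif denominators,
retained for type-level statistics). Reverse-complement pairing maps
X[N1/N2]Y to comp(Y)[comp(N1)/comp(N2)]X (an involution over the 96 motifs).
High-frequency motifs use a strict `>` against factor x 1/96 (factor 1 for
the broad tier, 2 for the hotspot tier). Per-type base values reuse the
hom = 1 / het = 0.5 weighting restricted to sites of one type or motif set;
A/T and C/G sites cannot move the [AT] value (it is pinned at 1 and 0
respectively), so only the four AT-changing types matter — asserted in the
tests.

## Private variants and derived rates

A site is private to the focal group iff (a) its derived frequency over
non-missing focal accessions is strictly between 0 and 1 and (b) every
non-missing call in the progenitor reference panels is one identical
homozygous allele, with panel missing rate ≤ 0.2 (mirroring the global
missingness policy). Heterozygous or conflicting reference calls disqualify
the site — strict fixity. Reference panels are per-subgenome: the D-carrying
progenitor group alone judges D sites. The donor is the fixed panel allele;
the derived rate of an accession is its mean derived-allele dosage over
qualifying non-missing sites, and group rates average over accessions (the
averaging order is over accessions; motif-direction pairs C→T and G→A are
averaged with equal weight). With finite panels some ancestral standing
variants drift to fixation in the panel and masquerade as private; at the
default panel sizes this contaminates < 1% of calls, and shrinks as panels
grow.

## LMM association scan

Model: y = μ + xβ + g + e with g ~ N(0, σg²K), e ~ N(0, σe²I). K is the
frequency-standardized dosage cross-product (VanRaden form) over
polymorphic markers, with per-site mean imputation of missing dosages — PSD
by construction. The scan eigendecomposes K once, estimates δ = σe²/σg² by
REML under the intercept-only null on a 61-point log grid over e^[−8, 8]
with bounded local refinement, and reuses δ for every marker (the
single-spectral-decomposition speed path of exact mixed-model association).
Each marker is tested by GLS in the rotated model; p-values come from the
exact t distribution with n−2 degrees of freedom. With K = I the scan
reduces to per-marker OLS to machine precision, which the tests assert at
1e-8. Non-PSD K is clipped to the nearest PSD with a warning; monomorphic
markers are skipped. LD pruning is PLINK-style (window 50 SNPs, step 50,
r² > 0.3 removes the later site) iterated to a fixed point so the operation
is idempotent. Significant markers (−log10 p ≥ 6, the printed threshold, not
recomputed from marker count) merge into loci within 5 Mb; candidate
intervals span all same-chromosome SNPs with r² > 0.6 to the peak; candidate
genes must show TPM strictly > 1 in both root and shoot. PC sign is
arbitrary, so the [AT]–PC1 correlation is reported as |r| (a signed variant
orients PC1 by the first accession's deviation).

## Synthetic-data model

The generator produces the statistical structure the pipeline measures while
staying site-wise — no coalescent, recombination maps, or read-level
simulation. Defaults are the test-scale study conditions: six chromosomes
(1A–2D) of 2 Mb at GC 0.46, six panel groups (wild emmer 15, durum 10,
*Ae. tauschii* 15, two landrace groups of 10, varieties 15), ~5k SNPs per
subgenome, residual heterozygosity 0.02 and missingness 0.02 (inbred,
well-genotyped material).

**Strata.** Each subgenome's variants belong to one of three strata:
*standing* (shared ancestral polymorphism, alternate-allele frequency
~ Beta(2, 2) — a mid-frequency ascertained-variant model chosen so that
panel-scale drift to fixation stays rare), *wild-branch new* (private to the
wild progenitor group) and *domesticated-branch new* (private to the
bread-wheat groups). Branch budgets are equal (1250/subgenome) so that with
equal rate multipliers the wild and domesticated branches are exchangeable —
the symmetric null for every [AT]-increase statistic. The per-subgenome
**rate multiplier** (default D = 1.5, A = B = 1) scales both the
domesticated-branch site count and the per-lineage derived dosage: a faster
mutational process accumulates more sites and more derived mass, so the
multiplier ordering shows up in both Δ[AT] and the private derived rate
(the monotonicity tests sweep multipliers 1→2). Branch-new variants have a
within-branch derived frequency of 0.25 (recent but post-bottleneck drifted);
domestication bottlenecks additionally fix a fraction 1−0.9 of standing
variants per domesticated lineage (bread wheat jointly, durum separately).

**Spectrum.** All strata share one mutational machinery: 6-type base rates
(A/G and C/T 0.30 each, A/C and G/T 0.11, A/T and C/G 0.09, before hotspot
boosting), a GC→AT directional bias of 0.9 (probability that the ancestral
allele of an AT-changing mutation is the G/C member), strand assignment with
probability 0.5, and x5 motif hotspots at five C→T contexts (A[C/T]G,
C[C/T]A, T[C/T]G, G[C/T]G, A[C/T]A) plus, by strand symmetry, their A/G
reverse complements. Hotspots apply to every stratum because context
preference is a property of the machinery, not of a branch; this also makes
the hotspot tier visible in both the common and the private SNP sets, as the
analysis expects. With these rates the hottest non-hotspot motif sits at
~0.013 and the coolest hotspot at ~0.045 against the 2/96 ≈ 0.021 threshold,
so exact recovery of the 10-motif tier is robust to sampling noise.
Positions are sampled without replacement, weighted by the hotspot
multiplier, via an exact two-class sequential scheme (the weights are
binary). The reference genome carries the ancestral allele at every site —
a reference-as-ancestor simplification.

**Sweeps and GWAS signal.** Sweep intervals (two per subgenome, 200 kb)
receive extra domesticated-branch variants with full GC→AT bias and derived
frequency 0.8, emulating selection-driven high-[AT] clusters. Optional
causal markers (off by default) are standing A-subgenome sites whose
standardized dosage linearly shifts each bread-wheat accession's derived-
allele carriage probability at D-subgenome new variants, making the D [AT]
value heritable for association tests.

**Truth ledger.** Every emitted VCF record has a ledger row (stratum,
donor/derived, motif, drawn frequency); recovery tests score the pipeline
against it.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and haplotype structure
within subgenomes (sites are exchangeable given their stratum), homoeologous
exchange between subgenomes, alien introgression, ascertainment bias of real
SNP calling, reference bias, and error processes correlated across
accessions. Statistics that are site-wise averages (everything in this
pipeline except LD pruning and candidate intervals, which are exercised on
separately constructed LD structures) are insensitive to these omissions.

## Problem sizes

The default simulation (12 Mb, 75 accessions, ~16k SNPs) runs in about two
seconds; the 50-seed recovery loops in the acceptance suite and the
acceptance script each complete in minutes on one core. The
private-variant recovery conditions are n = 30 focal accessions and 5k
domesticated-branch sites per subgenome with planted derived fractions
0.15/0.15/0.20; LMM calibration uses n = 60 with 500 markers per seed, and
power uses a 30%-variance marker against a two-block kinship background
(σ²: marker 0.3, polygenic 0.5, residual 0.2).

## Known limitations

* The classifier is deliberately minimal: no splice-site classes, no
  regulatory annotation, no effect-prediction parity with full annotation
  tools.
* Duncan letters assume interval-shaped non-significance along sorted means;
  the step-down procedure guarantees this internally but pathological
  tie-patterns can make letter displays of any MRT ambiguous.
* The LMM reuses the null-model variance ratio across markers (the standard
  speed path); per-marker REML would differ slightly for markers with very
  large effects.
* Private-variant precision is bounded by progenitor panel size (standing
  variants fixed in the panel by drift are indistinguishable from new
  mutations), a property of the definition itself rather than of the
  implementation.
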