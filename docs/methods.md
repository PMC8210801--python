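# Methods

This document records the statistical models implemented in `loadscape`,
the package's parameter defaults and why they were chosen, and the known
limits of the simulator. All problem sizes quoted here are the package's
own desk-scale design choices: scenarios are sized so that every claim in
the test suite can be recomputed from scratch in minutes on one core.

## 1. Forward Wright–Fisher simulator (`simdata`)

Diploid individuals, discrete generations, multiplicative fitness across
sites. A genotype at a site with selection coefficient `s` and dominance
`h` has fitness 1, 1 − hs, or 1 − s for 0/1/2 copies of the derived allele.
Parents are sampled proportional to fitness; each individual selfs with its
population's selfing rate, otherwise two parents are drawn. Gametes are
formed with free recombination between sites (each site segregates
independently), a deliberate simplification — see §8. Populations split by
spawning from population 0 at configured generation offsets.

**Initialisation.** `init="coalescent"` (default) seeds the founder
population from an msprime coalescent sample at the scenario's θ, then
burns in `max(150, N/4)` generations so selection and selfing reach their
own equilibrium around the neutral standing variation. `init="monomorphic"`
starts from no variation and burns in `10 N` generations, the classical
mutation–drift equilibrium warm-up; it is exact but unaffordable for large
2N at desk scale, which is why the coalescent route is the default.

**Distribution of fitness effects.** Each new coding mutation draws an
impact class with probabilities (HIGH, MODERATE, LOW) = (0.25, 0.5, 0.25),
then an alternate allele that realises that class given the codon context;
non-coding mutations are MODIFIER. Because many codon positions admit no
stop-gain substitution, the realised fraction of HIGH mutations is ~1% of
coding mutations regardless of the 0.25 target weight. Selection defaults:

| class    | s     | h   | interpretation                         |
|----------|-------|-----|----------------------------------------|
| HIGH     | 0.5   | 0.0 | severe recessive loss of function      |
| MODERATE | 0.03  | 0.2 | mildly deleterious, partially recessive|
| LOW      | 0.003 | 0.3 | nearly neutral                         |
| MODIFIER | 0     | 0.5 | neutral                                |

Full recessivity of HIGH variants is the biologically standard model for
severe loss-of-function alleles and is load-bearing: with even h = 0.05,
heterozygous selection (hs ≈ 0.025) removes HIGH variants from a 2N = 2000
population before they segregate, and no potential-load contrast can exist
at any scale.

**Genome architecture.** Defaults: 500 kb with 100 genes of 1.5 kb CDS
(plus intron/UTR structure), per-site mutation rate 2 × 10⁻⁷. The coding
fraction (~30%) is far above a real genome's so that HIGH-class variants
segregate in desk-scale simulations; at a realistic ~1% coding fraction a
500 kb replicate would carry essentially zero HIGH sites and load
comparisons would be vacuous.

**Truth bundle.** `write_truth_bundle` writes reference FASTA, GFF3 gene
models, a truth VCF (1-based, genotypes of the sampled individuals), a
pileup TSV, and a JSON config; all are byte-reproducible from the seed.

**Read simulator.** Per site and individual, depth ~ Poisson(mean_depth);
each read reports the true allele with probability 1 − e and one of the
three others uniformly otherwise (e = 0.01 default; mean depth 2.14
mirrors a low-coverage resequencing survey).

## 2. Genotype likelihoods and SNP calling (`genolik`)

For r reference and a alternate reads with error rate e, log-likelihoods of
(hom-ref, het, hom-alt) are `r ln(1−e) + a ln(e/3)`, `(r+a) ln(1/2 − e/3)`,
`r ln(e/3) + a ln(1−e)`. Sites are oriented to the major allele by total
read count. The minor-allele frequency is fitted per site by EM under an
HWE prior, clipped to [0, 0.5]. Calling retains sites with: polymorphism
LRT p < 10⁻⁶ (χ²₁), MAF ≥ 0.05, a minimum number of individuals with data,
a maximum summed depth, and a one-sided heterozygote-excess test p ≥ 0.01
(the classical paralog-collapse filter; the test fits a per-site F on
[−1, 1] and only penalises F < 0). Two named profiles mirror a ~2×
low-coverage survey: `population` (min 60 individuals, summed depth ≤ 500)
and `genomic` (min 15, ≤ 100). The depth caps are *summed* depths
calibrated for ~2× panels — higher-coverage analyses must pass explicit
`min_ind` / `max_depth` or the cap removes every site. Genotypes are called
as the maximum posterior under the HWE prior for individuals with ≥ 5 reads
(configurable).

## 3. Diversity, θ_W, and Ne (`diversity`)

The folded SFS is a histogram of minor-allele counts with bin 0 holding
monomorphic sites; passing `total_sites` adds the invariant remainder of
the assayed length so that site-bootstrap variance of S is honest (without
it, resampling a variants-only spectrum leaves S constant and the SE
collapses to 0). 100 bootstrap replicates are drawn as multinomial samples
over the spectrum — exactly equivalent to resampling sites with
replacement, without materialising invariant columns. Watterson's
θ_W = S / (a_n L) with a_n = Σ 1/i. Ne = θ_W / (4µ), with µ calibrated from
interspecific divergence (mismatch proportion / 2t, per year); the default
arithmetic is the literal year-based one, and a `generations_per_year`
factor is exposed for generation-time-aware estimates.

## 4. Kinship and inbreeding (`relatedness`)

KING-robust kinship uses only the joint genotype counts of a pair, making
it robust to allele-frequency misspecification and structure:
`(N(1,1) − 2[N(0,2)+N(2,0)]) / (N_het_a + N_het_b)`, with R0 (opposing
homozygotes per shared het) separating parent–offspring (R0 ≈ 0) from
full siblings at the same kinship. Degrees use the powers-of-two bins
(cutoffs 2^−1.5 … 2^−4.5). Pairs with fewer than 100,000 overlapping sites
are flagged unstable by default — a genome-scale floor; desk-scale runs
override it (the pipeline default is 200).

Individual F is fitted by maximum likelihood from genotype likelihoods
against population allele frequencies, with genotype priors
`P(0) = (1−f)² + f(1−f)F`, `P(1) = 2f(1−f)(1−F)`, `P(2) = f² + f(1−f)F`
(clipped, renormalised), maximised over F ∈ [−1, 1] by bounded scalar
search (tolerance 10⁻⁹). Bounded search rather than EM because the clipped
prior breaks EM's monotonicity guarantee. Small-sample caveat: frequencies
estimated from few inbred individuals attenuate F̂ toward zero (noisy f̂
understates expected heterozygosity); recovery experiments therefore use
≥ 50 individuals and replicate averaging.

PCA standardises genotypes per site as `(g − 2f)/√(2f(1−f))`, mean-imputes
missing entries, and eigendecomposes the individual × individual
covariance.

## 5. Differentiation and neutrality scans (`diffscan`)

Hudson Fst is accumulated as a ratio of sums — window numerator
`Σ[(p1−p2)² − p1(1−p1)/(n1−1) − p2(1−p2)/(n2−1)]` over denominator
`Σ[p1(1−p2) + p2(1−p1)]` — never as a mean of per-site ratios. Windows are
100 kb sliding by 50 kb by default. Z(Fst) standardises window Fst over
windows with at least 10 usable sites; |Z| > 5 flags outliers. Dxy is the
summed per-site `p1(1−p2) + p2(1−p1)` over window length. Fu & Li's D and
F compare total segregating sites (and π) against the singleton count with
the standard normalising coefficients; singleton excess (negative values)
indicates expansion or purifying selection, singleton deficit (positive)
indicates a bottleneck. Validation uses the package's coalescent generator
with step size changes (10× expansion, 95% bottleneck).

## 6. Genetic load (`loadcalc`)

Every biallelic SNP is classified against gene models by re-translating
the spliced CDS: stop gained/lost, start lost, and splice-dinucleotide
disruption are HIGH; missense MODERATE; synonymous and stop-retained LOW;
everything else MODIFIER. The exhaustive test enumerates all 3 × L
possible SNPs in a toy two-gene set (plus and minus strand, multi-exon)
and compares against an independent full-protein diff oracle.

Potential load of an individual is the fraction of a population's genic
segregating sites of a class at which it carries at least one alternate
allele; the population-level version is the class's share of segregating
sites. Realized load is the fraction of class alleles exposed as
homozygotes (`mode="hom"`, default) or carried at all (`mode="alleles"`).
Population contrasts use Welch's t (Satterthwaite df), with optional
Benjamini–Hochberg adjustment.

The central prediction, which the acceptance suite tests over 20
replicates: after a split into a large outbred population (2N = 2000) and
a small selfing one (2N = 100, selfing 0.3) sharing the same DFE, the
large population retains more segregating HIGH variation (higher HIGH
potential load — recessive severe alleles hide in heterozygotes), while
the small selfing population exposes more of its MODERATE/LOW variation as
homozygotes (higher realized load) and purges HIGH variants.

## 7. Alignment statistics (`seqdiv`)

For small sequence panels (e.g. mitogenomes): haplotype count and
diversity `Hd = n(1 − Σp²)/(n−1)`, parsimony-informative sites, per-site π,
and Kimura 2-parameter distance
`d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q)` with P/Q the transition and
transversion proportions. Columns with gaps or Ns are masked listwise by
default. Unequal panels are compared by drawing equal subsamples (n = 7 by
default) 100 times and reporting the empirical two-sided p of the
statistic difference; a Welch t on the permutation distributions is
reported as a clearly-labelled secondary output because permutation draws
are not independent samples.

## 8. Known limits of the simulator

- **Free recombination** between sites: no linkage disequilibrium, so LD-
  based analyses are out of scope; diversity, load, and kinship statistics
  are unaffected at the scales simulated.
- **Dense coding fraction and high µ** (see §1) trade genomic realism for
  observable counts of selected variants at desk scale.
- The read simulator has **no mapping bias, indels, or base-quality
  structure** — a single global error rate.
- Coalescent seeding approximates the selection–drift equilibrium by a
  neutral one plus a finite burn-in; the residual discrepancy is invisible
  at the package's tolerances but would matter for precise fixation-rate
  studies.
- `true_F` under `track_pedigree=True` is pedigree coancestry (O(N²) per
  generation); with `track_pedigree=False` a cheap selfing-chain recursion
  is used instead, which ignores biparental inbreeding through drift.

## 9. Numerical choices

- All likelihood work is done in natural logs, normalised per triplet
  before exponentiation; mixtures are floored at 1e-300 before `log`.
- EM for allele frequencies: tolerance 10⁻⁸, ≤ 200 iterations, init 0.25,
  frequencies clipped to [0, 0.5].
- Bootstraps default to 100 replicates; SFS bootstraps use multinomial
  draws (equivalent to site resampling) for speed.
- Window statistics use 0-based half-open windows; the final window is
  clipped to sequence length.
- Seeds are explicit everywhere; identical configs produce byte-identical
  truth bundles.
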