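# Methods

This note records the statistical models implemented in `paleoselect`, the
defaults and why they were chosen, what the synthetic-data generators do and
do not emulate, and the numerical conventions that matter for
reproducibility.

## Frequency estimation from sparse diploid calls

Ancient cohorts deliver few individuals with heavy, heterogeneous
missingness.  Allele frequencies are therefore estimated per population as
k/n with n = 2 × (individuals with a call); missing genotypes reduce n
rather than being imputed, and a population with no called alleles is
reported as "no data", never as frequency 0.  Confidence intervals are exact
Clopper–Pearson (beta-quantile) bounds: conservative, valid at any n, and
well behaved at k = 0 and k = n where normal approximations fail.  Wilson or
mid-p intervals would be narrower; for samples of ten-odd individuals the
conservative choice is the safer default.

Dataset filtering follows the plink convention and its order semantics:
individuals whose missing fraction exceeds `--mind` (default 0.5) are
removed first, then minor allele frequencies are recomputed on the survivors
and variants below `--maf` (default 0.01) are dropped.  The order is fixed
because MAF on the pre-filter individual set would let high-missingness
individuals rescue or kill variants.

Between-population differences use the two-sided Fisher exact test with the
probability-mass criterion (all tables no more probable than the observed
one), the convention of `scipy.stats.fisher_exact`.

## Admixture-informed neutrality tests

**Expected-range binomial test.**  For offspring of parents x and y with
ancestry fractions a_x + a_y = 1, the neutral expectation is the mixed CI:
f_exp_lower = f_x_lower·a_x + f_y_lower·a_y and likewise for the upper
bound.  Two one-sided binomial tests are run on the observed offspring
count: the inclusive lower tail P(X ≤ k | n, f_exp_lower) detects a deficit,
the inclusive upper tail P(X ≥ k | n, f_exp_upper) an excess; the minimum is
reported and called significant below 0.05.  These directions are the only
reading under which rejection corresponds to the observed CI falling outside
the expected range.  No multiple-testing correction is applied to the
minimum — the procedure is deliberately faithful to the two-tests-keep-the-
smallest construction — so it is mildly anti-conservative; the calibration
test bounds its neutral rejection rate at ≤ 10% and measures ~0.3% in
practice (the mixed-CI range is itself wide).  Inclusive tails are used
because the tail convention is otherwise arbitrary and inclusive tails are
the conservative choice.

**Empirical outlier test.**  The statistic is Δ = F_exp − F_obs with F_exp
mixing the parental *point* estimates (the statistic is a single difference
per variant; CI bounds play no role here).  The null is the empirical
distribution of Δ over variants in putatively neutral regions; the 2.5% and
97.5% percentiles (linear interpolation between order statistics, with
nearest-rank available as an option) are the significance thresholds.
Because drift, bottlenecks and the admixture itself act identically on
neutral variants, they are absorbed into the null by construction; the test
flags ~5% of neutral loci mechanically.  A floor of 100 variants is enforced
before a null is built ("underpowered null" otherwise).  Chained admixture
events are evaluated per event with the downstream parents' observed
estimates — uncertainty is not propagated through earlier events.

## Neutral-region construction

Intervals are 0-based half-open throughout (BED native; VCF positions are
converted at I/O boundaries only).  The cascade: genes buffered by 100 kb
(≈0.1 cM at the human average) are subtracted from the whole genome, then
segmental duplications, CNVs, conserved elements, CpG islands and repeats
(unbuffered — the buffer models linkage to selected coding sites, which the
other feature classes are not), then centromeres and 40 kb at each
chromosome end; fragments shorter than 1 kb are dropped (length exactly 1 kb
is kept).  All exclusions are unioned before subtraction, so their order is
immaterial.  The module consumes whatever BED files it is given; it does not
fetch annotations, and no attempt is made to reproduce any specific
reference genome's region set.

## SFS statistics

All statistics run on a binary haplotype matrix (0 = ancestral, 1 = derived
when polarised).  Sites with any missing call are dropped before computing a
statistic (complete-case), matching the use of imputed, complete panels; π
is reported as a mean pairwise difference *count*, not per-site (Tajima's D
is scale-free and counts avoid window-length conventions).

**Tajima's D** uses the standard constants (a1, a2, b1, b2, c1, c2, e1, e2)
and D = (π − S/a1) / √(e1·S + e2·S(S−1)).  S = 0 returns an explicit
"undefined", never 0; the degenerate n = 2 and n = 3 cases, where π ≡ S/a1
makes both numerator and variance vanish, return the algebraic limit 0.
Significance comes from the beta-distribution approximation to the null
density of D (D rescaled to (D_min, D_max) with mean 0 and variance 1);
classes are none / P<0.05 / P<0.02 / P<0.01, two-sided.

**Fu & Li's D and F** are the outgroup versions, contrasting total mutations
η (D) or π (F) against external-branch mutations η_e (derived singletons),
with the corrected variance constants in standard use (the widely adopted
fix to the original u_F).  Unpolarised input is rejected rather than
silently falling back to the within-sample starred variants.  Significance
is a two-sided empirical p from a seeded neutral-coalescent null (msprime,
no recombination) conditioned on the data-estimated Watterson θ, with the
D and F draws shared per panel and a +1/m continuity term.  The published
critical-value tables were considered as a default but are not shipped:
their entries could not be verified against any source available to this
package, and an unverifiable constant table is worse than a reproducible
simulated null.

**Haplotype-specific statistics** split the panel into carriers and
non-carriers of the focal allele, excluding the focal column itself from
both classes (it is monomorphic within each).  Classes below 4 haplotypes
are flagged underpowered and reported as "not computed" by the pipeline
rather than dropped silently.

**Sliding-window Tajima's D** uses half-open windows anchored at the region
start (defaults 40 kb window, 100 bp step); empty or monomorphic windows
emit "undefined".

**F_ST** defaults to the Hudson estimator with finite-sample correction;
multi-site scopes combine as ratio of averages (mean numerator over mean
denominator), the combination with the least bias.  Weir–Cockerham
(allele-count form) is available as an option.  Because the corrected
numerator can dip below zero at weak differentiation while the parameter is
non-negative, estimates are truncated to [0, 1]; sites monomorphic in both
populations are excluded, and an all-excluded scope is undefined.

**HWE** is the exact conditional test: conditioning on allele counts, all
heterozygote counts whose conditional probability does not exceed the
observed one contribute to p.  Computed in log-space for stability.

## LD structure and EHH

D′ and r² come from two-locus haplotype counts (complete-case per pair)
after site filters of MAF ≥ 0.05 and missingness ≤ 0.25.  The D′ confidence
interval is the likelihood-profile construction used by block-finding tools:
the multinomial likelihood of the four haplotype counts is evaluated on a
|D′| grid (allele frequencies at their estimates, sign fixed at the observed
sign), normalised, and 5% of the mass is accumulated from each end with a
one-grid-point step back toward the interior ("step-out" bounds).  Gabriel
blocks then classify a pair as strong LD when CI lower ≥ 0.70 and upper ≥
0.98, as strong recombination when upper < 0.90 (only such pairs are
informative), and accept a candidate site run when its bounding pair is
strong LD and ≥ 95% of its informative pairs are strong LD; maximal
non-overlapping blocks are chosen longest-span first, leftmost on ties.
All four thresholds are arguments.

EHH at position x is the probability that two random carriers of the core
allele are identical over [core, x]: Σ_g C(n_g,2) / C(n_c,2) over identity
groups, computed outward in both directions at every site (no
interpolation grid).  A missing call makes a haplotype unique from that
point on — conservative, deterministic.  EHH is 1 at the core and
non-increasing with distance by construction; curves are summarised by the
trapezoid area over physical distance when two alleles are compared.

## Synthetic data

**Admixture genotype generator.**  Parental frequencies per neutral locus
are uniform on [0.05, 0.95] (the broad range of an ascertained SNP panel);
the offspring founder frequency is α·f_x + (1−α)·f_y; optional Wright–Fisher
drift binomially resamples the offspring frequency for a configured number
of generations at 2·N_e alleles (default N_e = 10,000, human-scale);
diploid genotypes are binomial draws; missingness is independent per
genotype (default 0 — ancient-style sparsity is opted into, e.g. 0.3).  The
focal locus is appended last (defaults f_x = 0.05, f_y = 0.15, the
low-but-present starting regime of interest) and is the only locus
selection touches: f′ = f(1+s)/(1+fs) deterministically each generation
before drift.  Default cohort sizes are 50 individuals per population —
the order of an ancient-DNA population sample.

**Forward haplotype simulator.**  Founders carry neutral standing variation
drawn from a coalescent sample (msprime) at founder N_e = 5,000 with μ = r =
10⁻⁸ /bp/gen over 200 kb — θ ≈ 2×10⁻⁴/bp, human-like diversity at desk
scale.  The focal derived allele is grafted onto the carriers of the founder
variant whose frequency is closest to the configured 0.05, giving a
single-origin allele on a realistic LD background.  Forward generations
(default 100, roughly the post-admixture timescale of interest) sample 500
haplotypes by fitness (1+s genic selection), with single-crossover
recombination at probability r·L per meiosis and infinite-sites mutation
(collisions redrawn).  Parent choice is inverse-CDF sampling on common
uniforms, so runs differing only in s share every random draw — seed-paired
comparisons across selection coefficients are genuinely paired.  Loss of the
focal allele is reported distinctly (`focal_extinct`), not raised, so
replicate studies can count extinctions.

What the generators do **not** emulate: read-level ancient-DNA damage,
imputation bias against singletons (both act upstream of this package's
input contract), population structure beyond two-way admixture,
variable-rate recombination maps, and population sizes at real human scale
(the forward population of 500 is a desk-scale compromise; 2Ns is realistic
even though N is not).  Passing tests therefore show the statistics behave
correctly under the assumed model, not that any particular empirical
dataset would reproduce.

## Problem sizes and numerical conventions

The calibration and power studies run at: 1,000 neutral loci with 50
individuals per population (admixture calibration); 1,000 coalescent
replicates of n = 20 at θ = 10 (neutral Tajima's D band and type-I rate);
100 forward-sweep replicates at s = 0.05 (directional power, conditioned on
a segregating focal allele and both classes ≥ 4 haplotypes).  Percentiles
use linear interpolation; the D′ grid has 200 steps; empirical p-values
carry a +1/m term so they are never zero; all seeds are explicit function
arguments and fixed in tests.

## Known limitations

The expected-range test ignores drift between parents and offspring by
design (the empirical outlier test exists precisely to absorb it).  The
Fu & Li null conditions on Watterson's θ from the data, which is standard
but approximate.  Gabriel block boundaries are sensitive to the D′ CI
construction at small carrier counts.  The forward simulator's single
crossover per meiosis caps recombination realism at desk scale.
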