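# Methods and design notes

This note documents the models implemented in `flockld`, the choices made
where the design was genuinely open, and what the synthetic-data validation
does and does not demonstrate about real SNP-array data.

## Data model and conventions

Genotypes are allele dosages `x ∈ {0, 1, 2}` counting copies of a designated
reference allele, with a dedicated missing sentinel (stored as int8 −1 behind
the named constant `MISSING`; every computation masks before arithmetic, so
the numeric code never enters a sum). Coordinates are 1-based inclusive base
pairs in the PLINK `.map` convention, and every pair distance is the plain
difference `|bp_i − bp_j|`. Haplotypes are rows of `{0, 1, MISSING}` tagged
with a carrier individual and a parental origin (paternal/maternal/unknown);
the number of rows `n` is the chromosome sample size used by the Ne
estimator. Sex-chromosome and unmapped markers are dropped at load time with
counts reported, so all analyses run on autosomes only.

The PLINK text reader counts dosages against the first allele observed per
SNP (the usual convention when no allele annotation accompanies the file)
and re-polarizes downstream where needed; passing `ref_allele=` fixes the
counted symbol instead, which is what the package's own writer emits and
what makes a write/read round trip exact. A genotype with one missing allele
is treated as fully missing.

## Quality control

The protocol is the standard two-stage one for array data, ordered to retain
as many markers as possible: individuals with more than 10% missing
genotypes are removed first, then markers are filtered sequentially by call
rate (≥ 0.95), minor allele frequency (≥ 0.05) and Hardy–Weinberg
equilibrium (p > 1e-5). A marker removed at one step is not re-tested at the
next, so the ledger decomposes total loss by cause; ledger arithmetic
(remaining = previous − removed) is asserted on construction. All thresholds
are inclusive exactly as written.

The HWE test is the exact conditional test (Wigginton-style): conditional on
the sample size and the allele count, the p-value is the summed probability
of every heterozygote configuration no more likely than the observed one.
It is exact at the small per-genotype counts where the chi-squared
approximation fails; a chi-squared variant is available behind a flag. The
implementation is checked against a full-enumeration oracle for every
genotype table with n ≤ 25.

Mendelian cleaning targets the only trio-free check a daughter design
allows: sire–daughter opposing homozygotes. The daughter's genotype is
blanked; when one sire conflicts with more than 5% of his genotyped
daughters at a SNP the sire's genotype is blanked instead (a sire genotyping
error explains many conflicts at once — the choice of whose genotype to
blank is this package's own, as is the 5% default; both are configurable).

Imputation of missing daughter genotypes is deterministic: the paternal
allele distribution comes from the sire genotype (certain when homozygous,
½/½ when heterozygous), the maternal allele from the current population
frequency, and the posterior is their convolution. The modal genotype is
written only when its posterior reaches `accept_prob` (default 0.95) — the
acceptance threshold exists precisely to avoid over-imputing the most
frequent allele. After each full pass the frequencies are re-estimated from
the updated matrix, and ten passes are run. Observed genotypes are never
overwritten, and imputed dosages are Mendelian-consistent with the sire by
construction; on simulated truth the accuracy of accepted imputations is at
least the acceptance threshold up to sampling noise.

## Haplotypes

Statistical phasing (haplotype-graph HMMs) is out of scope. Instead the
package deduces alleles only where transmission forces them: homozygous
daughters phase themselves; a heterozygous daughter with a homozygous sire
has her paternal allele forced; everything else stays missing. Because the
rules fire only when forced, every deduced allele equals the true
transmitted allele on simulated data — an exact property, tested with no
tolerance. Pipelines that need complete haplotypes (LD, blocks, Ne) use the
simulator's true phase.

For LD the haplotype sample is made approximately independent by keeping
each sire's two haplotypes and each daughter's maternal haplotype; the
daughters' paternal haplotypes would re-count the few sires' chromosomes
hundreds of times.

## Pairwise LD

D′ and r² are computed by direct counting over the haplotypes jointly
non-missing at both SNPs. Pairs in which either locus is monomorphic within
that joint sample are undefined and excluded from every summary rather than
scored zero. Summaries use |D′|. The confidence bounds for block calling
come from the multinomial likelihood of the four haplotype counts evaluated
on a |D′| grid (step 0.001) with allele frequencies fixed at their MLEs:
after normalizing the likelihood to unit mass, CL is the largest grid value
with ≤ 5% of the mass strictly below it and CU the smallest with ≥ 95% at or
below it. Decay tables use half-open physical-distance bins with edges at
10/20/40/60/100/200/500 kb and 1/2/5/10/20/50 Mb; the half-length of r² is
read off 1-Mb bins by linear interpolation between the two bin midpoints
straddling half the first bin's mean, and the computation errors rather than
extrapolates when the curve never falls that far. Non-syntenic background LD
samples ⌈5%⌉ of the SNPs per chromosome (seeded, without replacement) and
summarizes all between-chromosome pairs.

All-pairs statistics are computed chromosome-at-a-time with dense matrix
products, so memory scales with the square of one chromosome's SNP count,
never with the genome-wide pair count.

## Haplotype blocks

Only the core Gabriel criterion is implemented: a candidate span qualifies
when its outermost pair is in strong LD (CU > 0.98, CL > 0.70) and at least
95% of its informative pairs (strong-LD or recombination) are strong;
candidates are accepted greedily by decreasing physical span with leftmost
tie-break, skipping overlaps. The size-stratified sub-rules that some GUI
implementations add for 2–4-marker blocks are deliberately omitted; the
thresholds are configurable instead. No span cap is applied by default
(long blocks are legitimate in livestock genomes); the pipeline classifies
pairs within a configurable marker window (default 40 SNPs), which bounds
the quadratic confidence-bound computation and caps callable block length at
the window — safe for array data where blocks span few markers.

The greedy caller is verified against an exhaustive-candidate oracle on
random chromosomes of ≤ 25 SNPs across 150 seeds. One plausible-sounding
invariant is deliberately *not* asserted: raising the strong-LD fraction can
slightly increase total blocked length, because removing a long candidate
can free its markers for shorter non-overlapping blocks whose spans sum
higher. The monotone property that does hold — the qualifying-candidate set
shrinks as the fraction rises — is what the suite asserts.

## Effective population size

Each physical distance is converted to Morgans under one of three modes —
uniform 1 cM/Mb, a single genome-average rate, or per-chromosome rates
supplied as configuration — and pairs are sorted by genetic distance and
stacked into 1,000-pair bins (final partial bin dropped). Per bin,
`Ne = (1/(r̄² − 1/n) − 1)/(4c̄)` and `T = 1/(2c̄)`; bins with `r̄² ≤ 1/n`
are reported as undefined rather than clamped. Requested time points are
served by the bin with the nearest T (ties toward the larger T); the default
grid {1, 5, 10, 15, 25, 50, 75, 100, 150, 200, 250} spans recent to ancient
history and is configurable. An optional generation interval (default
4 years) converts T to years.

Two properties of this estimator matter for interpreting trajectories, and
both are visible in the validation runs:

* **Memory window.** LD at distance c reflects roughly the last
  `1/(2c + 1/(2N))` generations, so nothing older than about `2N_recent`
  generations is recoverable, and a deep bottleneck overwrites the ancient
  signal at all distances. The declining-trajectory validation therefore
  uses a gradual decline placed inside the observable window and checks a
  rank correlation between recovered and true sizes, not absolute agreement.
* **Sample-generation effects.** The genotyped cohort of a breeding scheme
  sits a generation or two below the breeding population, in a census far
  larger than Ne; those nearly drift-free meioses decay large-c LD and so
  inflate the most recent (smallest-T) estimates. The worked example shows
  exactly this at T ≈ 1–5.

On constant-Ne=100 simulations the median recovered Ne over T ∈ [5, 50] is
within ±25% of truth (typically +5 to +20%; the inversion formula is known
to run slightly high against forward simulations).

## Inbreeding

Pedigree F uses the Meuwissen–Luo algorithm: for each animal, trace its
ancestor list youngest-first, accumulating `L²·d` contributions to the
relationship-matrix diagonal, where `d` is the Mendelian-sampling variance
given the parents' F. Unknown parents are unique founders; founders are
non-inbred and unrelated. The implementation agrees exactly (to 1e-12) with
an independent recursive-kinship oracle on random small pedigrees and
reproduces the classical values 0.25 / 0.125 / 0.0625 for parent–offspring,
half-sib and first-cousin matings.

Marker F uses the three GCTA `--ibc` estimators with the analyzed sample as
its own base population by default (an external frequency vector is accepted
for truth-based tests). Each individual's denominator counts only its own
non-missing SNPs; SNPs with frequency 0 or 1 are excluded with a warning.
Negative estimates are expected when sample frequencies stand in for base
frequencies; clamping to zero happens in trend *reporting* only, never in
stored values. The trend table reports per-birth-year means and the fraction
of individuals above 0.0625 (the first-cousin level conventionally flagged
as high).

## The simulator

A forward Wright–Fisher model was chosen over a coalescent because the
half-sib family structure, true phase and per-meiosis transmission records
fall out directly. Discrete generations of `N(t)` diploids (piecewise-
constant trajectory); two parents per offspring drawn uniformly with
replacement; founders in linkage equilibrium with frequencies uniform on
[0.1, 0.9]; no mutation afterwards, so allele bookkeeping is exact (array
sites are pre-ascertained polymorphisms, which this emulates). Recombination
is a no-interference crossover process realized marker-to-marker by Haldane
switch probabilities `r = (1 − e^{−2d})/2` per adjacent interval — exactly
the marker-resolution marginal of Poisson-count, uniformly-placed
crossovers. Burn-in of `4·N(0)` generations precedes the trajectory epoch so
LD equilibrates.

Because drift without mutation fixes loci (heterozygosity decays by
`e^{−t/2N}`, which over a 4N burn-in leaves only a small polymorphic
fraction), the simulator seeds `candidate_snp_factor` × the target panel
size in candidate loci and the ascertainment step — dropping SNPs below the
MAF floor in the genotyped sample, then evenly thinning survivors to the
target — plays the role a discovery panel plays in real array design.

The half-sib sample selects sires from the final generation and creates each
daughter by true meioses from her sire and a distinct, freshly-bred dam (the
census cohort one generation below the breeding population, as in a real
flock where census ≫ Ne). Genotypes can then be degraded with independent
per-entry missingness and genotyping error (an erroneous entry becomes one
of the two other dosages uniformly). Everything is deterministic given the
seed.

Default scale is a desk-top one: four 100-cM chromosomes, a 500-SNP target
panel per chromosome from 2,000 candidates, N ≤ 150 with a gradual decline
to 60, and 8 sires × 40 daughters — sizes chosen so a full pipeline run and
the validation suite complete in minutes on one CPU while leaving every
qualitative behaviour (LD decay, block structure, Ne trend, trio-free
cleaning) observable.

### What the synthetic validation does not show

The simulator has no genotype-intensity model (QC starts from called
genotypes), no selection, migration or overlapping generations, no sex
chromosomes, and a physical map that is uniform per chromosome — so it
cannot probe assembly errors, recombination hot-spots, or ascertainment
biased toward specific breeds, all of which affect real chip data. Marker
density per cM is far below a real 50k chip, so the shortest decay bins
(< 40 kb) are usually empty at desk scale and per-chromosome "r² < 100 kb"
summaries may be undefined. Passing tests certify the estimators against
their own model assumptions, not against platform artifacts.

## Numerical choices

* HWE enumeration in log-gamma space, renormalized; configurations equal to
  the observed probability are included in the tail (tolerance 1e-12).
* The |D′| likelihood grid is linear with step 0.001; haplotype-probability
  clipping at zero handles boundary cells with zero counts.
* Ne inversion guards the singularity `r̄² ≤ 1/n` by reporting "undefined";
  negative Ne is likewise undefined, never clamped.
* Pair statistics use float64 matrix products; undefined entries (N < 2 or
  monomorphic) are NaN and filtered, never zero-filled.
* Pedigree cycle detection is Kahn's algorithm; the error names one cycle.
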