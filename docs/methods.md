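# Methods

This note records the models implemented in `balsel`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the package's known limitations.

## Scope and data model

All analyses operate on phased biallelic SNPs.  Coordinates are 1-based
inclusive (VCF convention) throughout; half-open intervals are converted
at the boundary.  Multiallelic records, indels, and records with missing
genotypes are excluded at read time with logged counts; an unphased
heterozygous genotype is an error rather than an exclusion, because phase
is load-bearing for every haplotype-based statistic downstream.  Ploidy
is fixed at two.  The transcript (gene model + reference CDS) is
caller-supplied; the package contains no transcript-selection logic.

## Annotation and polarization

Codon consequence is computed on the coding strand with the standard
genetic code; a variant is synonymous iff the reference and alternate
codons translate identically, and changes creating a stop are classed
nonsense and excluded from McDonald–Kreitman counts.  Ancestral state is
assigned only when *all* supplied outgroup alleles agree and match one of
the two human alleles; disagreement or a third state leaves the site
unpolarizable, excluding it from Fay & Wu's H and iHS rather than
majority-calling.  The pooled MAF is computed over all gene copies
(count-weighted across groups) and folded at 0.5.

## Scan statistics and empirical-rank significance

F_ST defaults to the Weir & Cockerham (1984) variance-components
estimator on allele counts (slightly negative values are possible and
preserved); Hudson's two-population estimator is available behind a
flag.  Tajima's D uses the standard constants; Fay & Wu's H is reported
unstandardized by default (θ_π − θ_H), with the normalized variant behind
a flag.  Monomorphic sites are flagged undefined and excluded from rank
distributions.

Empirical rank P-values use the inclusive rule: P = (number of window
sites with score ≥ the candidate's, the candidate itself included) /
(window site count), so the smallest attainable P is 1/window-size and
ties count toward the numerator.  Windows are centred on the candidate —
2 Mbp for scan statistics, 90.3 Mbp for the MAF-rank test — and clipped
at chromosome ends without re-expansion.  The MAF-rank test restricts
the window to biallelic nonsynonymous SNPs before counting.

Rank-P of a *discrete* per-site quantity (e.g. MAF itself) is only
approximately uniform under the null because allele-count ties are
common, particularly among singletons; the calibration tests therefore
rank a continuous score (iHS), matching how the windowed rank scheme is
used in practice.

## Haplotype homozygosity

EHH uses the unbiased pairwise definition: the probability that two
carrier haplotypes drawn without replacement are identical over all SNPs
between the core and the query position, computed by prefix-group
refinement (Σ C(k_j, 2) / C(K, 2)).  iHH is the trapezoidal integral of
EHH against physical distance (no genetic map in scope; a user map hook
can replace coordinates), truncated where EHH crosses 0.05 (the final
segment is linearly interpolated down to the cutoff) or at an inter-SNP
gap above 200 kb.  Raw iHS = ln(iHH_ancestral / iHH_derived); XP-EHH
integrates the population-level EHH over all haplotypes and compares two
populations (sign convention: first over second).  Cores need a MAF of
at least 0.05 for iHS.  Standardization bins derived-allele frequencies
into 20 equal-width bins and z-scores within bins; bins with fewer than
two scores or zero spread leave their sites unstandardized with a
warning.  P-values for z-scores are two-sided standard-normal tails.

## Contingency tests

The MK table counts within-species polymorphisms versus fixed
differences from a single outgroup CDS, split synonymous/nonsynonymous.
A position polymorphic within the sample is never simultaneously counted
as a fixed difference.  Codons differing from the outgroup at more than
one position are scored by enumerating all single-step mutational
orderings, discarding paths through stop codons, and averaging the
synonymous/nonsynonymous step counts.  The test statistic is Pearson χ²
without continuity correction (df = 1), with Fisher's exact test as the
zero-margin fallback.  The same uncorrected Pearson χ² is used for the
two-locus genotype-association table (rows/columns with zero margin are
dropped with df adjusted); on the worked 3×3 family-sample table this
convention reproduces χ² = 13.72, df 4, P = 0.0082.

## Poisson-random-field neutral expectation

Under the Poisson random field, standing neutral variation enters two
daughter populations at the ancestral frequency y with spectral density
θ·(2/y) dy, and the daughters drift independently for t coalescent units
(time in units of 2N generations).  The expected number of sites whose
derived allele remains at intermediate frequency in (x, 1−x) in *both*
daughters is θ·H_x with

    H_x = ∫₀¹ P⁰_y(x < ξ_t < 1−x)² (2/y) dy.

The interval-occupancy probability of the absorbing neutral Wright–
Fisher diffusion is evaluated by the classical eigenfunction expansion:
in u = 1−2y the eigenfunctions are Jacobi polynomials P⁽¹'¹⁾ with
eigenvalues i(i+1)/2, and integrating the transition density over the
symmetric interval telescopes into Legendre polynomials, leaving

    P⁰_y(·) = Σ_{i odd} y(1−y) (2i+1)/i · P⁽¹'¹⁾_{i−1}(1−2y)
              · e^{−i(i+1)t/2} · 2 P_i(1−2x)

(even-index terms vanish by the y ↔ 1−y symmetry).  The series is
truncated when a term magnitude falls below 1e−12; convergence needs
roughly √(60/t) terms, so double precision suffices for t ≥ 0.01, and
hitting the configurable cap raises an explicit error.  H_x is then an
adaptive quadrature (`scipy.integrate.quad`, absolute tolerance 1e−9);
the y → 0 endpoint is integrable because the squared occupancy
probability vanishes like y².  The closed form p(x) = 1 − exp(−θ·H_x)
uses expm1 for small exponents.

Two independent checks are built in: a forward binomial Wright–Fisher
Monte-Carlo oracle (2N gene copies, round(t·2N) generations) must agree
with the analytic occupancy probability within binomial error, and H_x
must be strictly decreasing in both x and t.

θ per gene is estimated by Watterson's θ_W = S/Σ 1/i when estimated at
all; the evaluation functions also accept user-supplied θ directly, so
externally estimated values can be plugged in unchanged.

## Synthetic-data generator

The forward simulator is a non-overlapping-generation diploid
Wright–Fisher model: viability selection on the target genotype
(fitnesses 1 : 1+s_het : 1, symmetric overdominance, equilibrium
frequency 0.5), random mating with selfing allowed, uniform
recombination (Poisson breakpoints per gamete, resolved by flip-parity
over ordered sites), and infinite-sites mutation (each mutation occupies
a brand-new continuous position; collisions are redrawn).  A neutral
burn-in of ≥10N generations precedes the placement of the target derived
allele (either at a chosen frequency or as a single copy), after which
the population splits into two daughters of size N that evolve
independently with a shared site registry.  Output is a phased sample
without replacement from each daughter plus a JSON-ready truth record
(target position, frequency trajectories, injection attempts).  Forward
(rather than coalescent) simulation was chosen because selection and
two-locus epistasis are first-class here and the oracle stays
self-contained.

Defaults describe a 20-fold rescaled human-like locus: N = 500 diploids
with μ = ρ = 5e−7 per bp per generation gives θ = ρ ≈ 1e−3 per bp, and
split_generations = 500 equals a divergence time of 0.5 coalescent
units — the out-of-Africa-scale two-population scenario (an ancestral
effective size of thousands diverging for half a coalescent unit).
Rescaling preserves the products Nμ, Nr and Ns, so tests that operate at
even smaller N raise s_het correspondingly.

The epistatic-couples generator draws a 3×3 genotype-pair table as a
single multinomial sample from the fertility-weighted Hardy–Weinberg
product distribution: couples form independently at each locus and
contribute offspring with weight 1 + s_match for designated compatible
genotype pairs (default: matched homozygote/heterozygote pairs on the
diagonal).  s_match = 0 yields exact independence, which is what makes
the null-calibration test of the association χ² meaningful.

What the generator does *not* emulate: realistic human demography
(growth, migration, bottleneck shapes), mutation-rate or recombination
hotspot heterogeneity, background or positive selection at other sites,
genotyping or phasing error, and cyclical sexual-conflict dynamics.
Passing calibration tests therefore demonstrates internal statistical
correctness of the estimators under idealized neutral/overdominant
models, not robustness to those real-data complications.

## Calibration experiment sizes

The simulation-based calibration tests use deliberately small rescaled
populations so the full suite stays quick: Tajima's D neutral
calibration uses 1,000 replicates of N = 50, L = 4 kb samples (the
statistic's well-known small-sample expectation is slightly negative, so
the ±0.1 band is checked around zero with this replication); rank-P
uniformity ranks per-site iHS within windows of ≈10–30 eligible sites
over 150 replicates; the genotype-association null uses 2,000 tables of
300 couples; the analytic-vs-Monte-Carlo grid uses N = 500 and 30,000
replicates per point (three binomial standard errors plus an O(1/N)
discreteness allowance).  The overdominance power experiment uses
N = 100, a 60 kb region with ρ = 2e−5 (so the swept haplotype,
roughly s/(r·ln 2Ns) ≈ 5 kb, decays well inside the window), a single
derived copy injected at the split under s_het = 0.5, and compares
|iHS| at the target 30–50 generations after establishment against
frequency-matched neutral sites: the sweep-like haplotype signature
erodes within ~0.5 coalescent units of reaching equilibrium, so the
scan's power is specific to *recently established* balanced
polymorphisms — old balanced polymorphisms are expected to show little
iHS signal.

## Known limitations

* EHH integration is over physical distance; without a genetic map,
  rate heterogeneity can masquerade as selection signal.
* The PRF expectation assumes a symmetric split (both daughters of the
  reference size evolving for the same t) and free recombination among
  sites (independent site histories).
* The MK implementation ignores polarized variants and within-codon
  haplotype phase beyond major-allele context when classifying
  polymorphisms; this matches standard practice but can misclassify
  rare multi-hit codons.
* Rank-P values are discrete; their resolution is limited by window
  site counts, and ties are counted conservatively (toward larger P).
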