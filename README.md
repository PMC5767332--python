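# balsel

Population-genetic analyses for detecting **balancing selection on coding
polymorphisms**, built around the signatures expected when heterozygote
advantage or compatibility selection holds a nonsynonymous variant at
intermediate frequency — the situation proposed for human
gamete-recognition genes, where sperm-expressed *C4BPA* and the egg-coat
glycoprotein genes *ZP3*/*ZP2* are thought to coevolve under selection on
sperm–egg compatibility.

The package is aimed at population geneticists who have phased biallelic
haplotypes (VCF), a gene model with a reference CDS, and outgroup alleles,
and who want to ask: *is this intermediate-frequency nonsynonymous site
a balanced polymorphism, and could it have arisen neutrally?*

## What it computes

* **Haplotype tabulation** — apply phased variants to a reference CDS per
  gene copy and count unique full-length coding haplotypes per population
  (`haplotype_io`).
* **Site annotation** — codon consequence (synonymous / nonsynonymous /
  nonsense), ancestral/derived polarization by unanimous outgroup
  comparison, per-group derived-allele frequencies and pooled folded MAF
  (`variant_annotation`).
* **Selection scans with empirical-rank significance** — Weir & Cockerham
  F_ST (Hudson's estimator optional), Tajima's D, Fay & Wu's H, and the
  rank-P scheme in which a candidate's P-value is the proportion of sites
  in a surrounding window (2 Mbp by default) whose score is ≥ the
  candidate's (`selection_stats`).
* **Haplotype homozygosity** — EHH decay curves, iHS
  (ln iHH_ancestral/iHH_derived), XP-EHH, and z-score standardization
  within 20 derived-allele-frequency bins (`haplotype_homozygosity`).
* **Contingency tests** — McDonald–Kreitman 2×2 tests against an outgroup
  CDS, and the two-locus genotype-association χ² for gametic
  disequilibrium between unlinked candidate sites (`contingency_selection`).
* **The windowed MAF-rank outlier test** — P = (number of biallelic
  nonsynonymous SNPs in a 90.3 Mbp window with MAF ≥ the candidate's,
  candidate included) / (total), (`maf_outlier`).
* **Poisson-random-field neutral expectation** — the expected number
  θ·H_x of sites whose derived allele segregates at frequency within
  (x, 1−x) in *both* of two populations that diverged neutrally t
  coalescent units ago,

      H_x = ∫₀¹ P⁰_y(x < ξ_t < 1−x)² (2/y) dy ,

  where ξ_t is a neutral Wright–Fisher diffusion with absorbing
  boundaries started at y, evaluated by the classical spectral
  (Jacobi/Legendre) expansion, plus p(x) = 1 − exp(−θ·H_x), the
  probability of at least one such site (`prf_neutrality`).  A forward
  binomial Wright–Fisher Monte-Carlo oracle validates the series.
* **Synthetic data** — a forward diploid Wright–Fisher simulator
  (infinite-sites mutation, uniform recombination, two-population split,
  symmetric overdominance at a target site) and an epistatic
  fertility-selection sampler for two-locus genotype tables
  (`synthetic_data`).

## Worked example

The shared-polymorphism neutral expectation for a candidate with minimum
group MAF x = 0.185 under a two-population divergence of t = 0.5
coalescent units, with a per-gene population mutation rate θ = 1.6333:

```bash
$ balsel prf --x 0.185 --t 0.5 --theta 1.6333
{
 "H_x": 0.8766599456042592,
 "p_x": 0.7611330768802198
}
```

H_x ≈ 0.877 means that per unit θ, almost one site is expected to show a
derived allele at frequency in (0.185, 0.815) in both populations under
neutrality alone; with θ ≈ 1.63 the probability of seeing at least one
such site is ≈ 0.76 — so an intermediate-frequency site with this bound
is *not* surprising under neutral out-of-Africa-style divergence.

The two-locus genotype-association test on a 3×3 table of observed
couple genotype counts (rows: copies of the derived allele at locus 1;
columns: locus 2):

```bash
$ printf '9,41,20\n151,242,80\n255,435,182\n' > couples.csv
$ balsel ld --table couples.csv
{
 ...
 "chi2": 13.72281832244616,
 "df": 4,
 "p": 0.008234329921429683
}
```

χ² = 13.72 on 4 df (P = 0.0082) rejects independence of the two loci'
genotypes: genotype combinations are non-randomly associated, as expected
under selection favouring compatible allele pairs at unlinked loci.

Simulating inputs and running the pipeline end to end:

```bash
balsel simulate haplotypes --seed 7 --out sim/
balsel report --config pipeline.yaml   # annotate → scan → prf → ld
```

## Layout

```
src/balsel/          library modules (one per analysis stage)
tests/               pytest suite, incl. simulation-based calibration
scripts/acceptance.py  headline-number reproduction
docs/methods.md      model assumptions, parameter choices, limitations
```
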