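# Methods

This note documents the statistical model behind `sweepscan`, the choices
made where the methods literature leaves the design open, and what the
synthetic data generator does and does not emulate.

## The scan statistics

All four statistics measure the decay of haplotype identity around a core
SNP in a phased panel, the classic signature of recent positive selection:
a beneficial allele rises faster than recombination can break up the
haplotype it sits on, leaving unusually long stretches of identity.

**EHH.** For the carriers of one core allele, EHH(x) is the probability that
two randomly drawn carrier haplotypes are identical at every segregating
site between the core and position x.  We compute it by successive
refinement of identity groups, one site at a time, as the fraction of
still-identical carrier pairs out of the pairs available at the core.  The
denominator is fixed at the core (C(n_c, 2)); a haplotype leaving the
comparison at its first missing genotype simply stops contributing identical
pairs.  This keeps every profile monotone non-increasing and exactly equal
to brute-force pair enumeration (tested).

**iHS.** iHH is the trapezoidal integral of EHH over physical distance,
truncated where EHH first drops below a cutoff (default 0.05, the default of
the standard calculators), with linear interpolation to the crossing.
Unstandardized iHS = ln(iHH_ancestral / iHH_derived).  Because young alleles
sit on long haplotypes even under neutrality, raw scores are standardized
within derived-allele-frequency bins (width 0.05, bins with fewer than 20
scored sites merged with their neighbour, sample sd).  Distances are
physical bp: no genetic map is assumed.

**nSL.** Identical in spirit, but tract length is counted in segregating
sites rather than bp, which removes the dependence on the recombination
map.  For a pair of carriers the tract is the maximal run of consecutive
segregating sites around the core over which the pair is identical; the
class score SL is the mean over carrier pairs.  Averaging over pairs makes
SL equal to 1 plus the sum of the EHH curve over site offsets on each side,
which is how it is computed; the equality is verified against an exhaustive
pair scan.  nSL raw = ln(SL_ancestral / SL_derived); same binned
standardization.

**XP-EHH and Rsb.** Between a cultivated and the wild population, the
allele-pooled site homozygosity EHHS replaces allele-specific EHH: all
haplotypes take part, initially grouped by their core allele, and the
profile is normalized to 1 at the core.  Two homozygosity estimators are
offered: the unbiased pair-count form (used for iES and XP-EHH, Sabeti-style)
and the biased sum of squared group frequencies (used for inES and Rsb,
Tang-style).  With complete data the two differ only by the (n−1)/n bias
factor and its normalization; we keep both so the two statistics remain
distinct estimators as in the rehh package.  XP-EHH = ln(iES_pop1/iES_pop2),
Rsb = ln(inES_pop1/inES_pop2), pop1 the cultivated population, standardized
genome-wide (no frequency binning — the statistics do not require ancestral
polarity).

**nSL extension cap.** Tract extension is capped at 100 segregating sites
per side (the default of the standard calculator); pairs still identical at
the cap contribute the capped length.

**Robust standardization.** The library default follows the textbook form
(sample mean/sd per bin).  The pipeline additionally offers — and its run
configuration enables by default — a trimmed variant: location and scale
from the middle 80% of each bin's scores, with the normal-consistency
factor for the sd.  The motivation is specific to small (simulated or
targeted) genomes: when the swept fraction of scored sites is not
negligible, the plain sd is inflated by exactly the outliers the scan is
meant to find, deflating every z.  A genome-wide scan over millions of
SNPs has an effectively uncontaminated sd, which the trimmed estimator
reproduces at small scale while leaving the null calibration intact.

**Sidedness.** P values are Gaussian tails of the standardized scores.
iHS and nSL have no fixed direction for population-specific adaptation and
default to two-sided.  XP-EHH and Rsb are directional by construction of
the wild-vs-cultivated contrast (population 1 is the cultivated
population, positive scores mean longer haplotypes there), and the
pipeline defaults to the upper one-sided tail for them; the library scan
functions default to two-sided, with sidedness exposed everywhere.

## Ancestral polarization

Ancestral states come from per-site allele-state tables of 7 related
species: the focal species plus its 3 closest relatives form the inner
(4-way) clade, all 7 the outer clade.  The ancestral allele is the allele
shared by ≥3 of the 4 inner-clade species, else by ≥4 of the 7; otherwise
the site is unresolved ("missing") and excluded from iHS/nSL while remaining
in XP-EHH/Rsb.  The focal species counts toward the consensus by default
(it is a member of both clades); a switch excludes it.  Ties fall through
to the outer clade, then to missing.  A consensus allele that matches
neither segregating allele is treated as missing.

## Fisher combination and FDR

Per SNP, the available method P values (1–4 of them — sites without an
ancestral call carry only XP-EHH/Rsb) are combined as T = −2 Σ ln Pᵢ,
chi-squared with 2n degrees of freedom under the independent null.  A strict
mode restricts to sites scored by all four methods.  Combined P values are
BH-adjusted genome-wide per population and sites with q < 0.01 are called
selective.  Selected sets are partitioned across populations into unique /
pairwise / shared-by-all groups by exact set algebra on (chrom, pos).

The four statistics are positively dependent in practice, so T is
anticonservative to an unknown degree; the same caveat applies to the
published analyses this pipeline follows, and the FDR threshold should be
read as a ranking device rather than an exact error rate.

## Annotation

Genes come from GFF3 gene features; the promoter is the 2-kb stretch
immediately 5′ of the TSS (strand-aware, clipped at chromosome bounds).
A selective site is genic if inside any gene body; promoter hits are
reported as a subset of the intergenic total (the counting convention of
the study design this mirrors), with a disjoint three-way mode available.
Overlap with externally supplied sweep regions uses 0-based half-open BED
containment of the 0-based site coordinate.

## Hard/soft classification

In a window of up to 201 SNPs centred on each selective site (truncated at
chromosome ends and flagged), the sorted haplotype frequency spectrum gives
H1 = Σpᵢ², H2 = H1 − p₁², H12 = (p₁+p₂)² + Σ_{i≥3}pᵢ².  The observed
(H12, H2/H1) point is compared with simulated hard- and soft-sweep scenario
sets; support for each class is the number of simulated points within
Euclidean distance 0.1 (strict inequality, raw coordinates — both axes are
already in [0, 1]), and the Bayes factor is the hard/soft support ratio:
BF > 1 → hard, BF < 1 → soft, BF = 1 or zero support on both sides →
unknown.  Zero soft support with positive hard support is reported as
BF = +∞, labelled hard.

## The synthetic generator

A diploid Wright–Fisher population of constant size N (default 500)
evolves forward with infinite-sites mutation (default μ = 1 × 10⁻⁷ per bp
per generation, the rate appropriate to the resequencing data this design
emulates), uniform crossover recombination (r = μ by default), and, at one
focal site, additive selection with fitness 1, 1+s/2, 1+s.

Scenario draws follow the study priors: s ~ U[0,1]; τ (time since selection
ended, in units of 4N generations) ~ U[0, 0.005]; soft sweeps start from a
standing neutral variant at frequency e ~ U[0, 0.2] (the segregating site
nearest the region centre with frequency closest to e becomes beneficial,
so its carriers have genuine neutral-equilibrium haplotype structure; the
realized e is recorded), hard sweeps from a de-novo mutation (e = 0).
Selection runs until the allele reaches f ~ U[e, 1], conditioning on
non-loss by rejection-resampling the selection phase from the same standing
population (attempt-capped), then the population drifts neutrally for τ·4N
generations before n haplotypes are sampled.  With s = 0 the focal allele
simply drifts, unconditioned.

**Initialization.** The population starts at the neutral mutation–drift
equilibrium frequency spectrum expectation (E[sites with i copies] =
4NμL/i), with carriers assigned at linkage equilibrium, then burns in for
`burnin` further generations (default N) of full forward simulation to
build linkage before any sweep is planted.  This reproduces equilibrium
diversity exactly (π ≈ 4Nμ, verified against an msprime coalescent oracle)
and short-range LD qualitatively, but haplotype *ages* are capped near the
burn-in depth: statistics contrasting allele ages against deep neutral
ancestry (iHS above all) see a compressed contrast at the default burn-in.
Tests of those properties use burn-in of a few N; routine panels keep the
default for speed.

**Scale.** Default region length L = 50 kb and sample size 60 haplotypes
for scenario panels (2,000 replicate panels simulate in a few minutes on
one CPU).  Note the desk-scale regime is *harder* than the original study
design it stands in for: with N = 500, 2Ns for the same s is orders of
magnitude smaller than with a realistic Ne, sweeps are slower relative to
drift, and a 50-kb region is a large fraction of a sweep's footprint.
Recovery rates measured on this generator are therefore conservative
relative to the full-scale design (3 cultivated populations × {hard, soft}
× 100,000 replicates of 200-kb regions; the grid helper reports this
design total).

**Cohorts.** For end-to-end runs the generator builds a small genome of
independently simulated chromosomes (default three of 250 kb).  Per
chromosome, an equilibrated ancestral population splits into one wild and
one or more cultivated populations (optional founder bottleneck); each
cultivated population diverges neutrally for `split_generations` (default
400, giving wild/cultivated differentiation of roughly F_ST ≈ 0.3) and
then carries its planted sweep on the designated chromosome, with
selection ending τ·4N generations before sampling.  The default planted
sweep is hard, s = 0.15 to f = 0.9, τ = 0 — a recently completed partial
domestication sweep whose footprint ≈ 1/(r·T_sweep) ≈ 40–80 kb occupies a
minority of its chromosome and a small fraction of the genome.  The sizing
argument: the scan standardizes within the cohort and needs a neutral
majority; a single region swept wall-to-wall is undetectable by
construction, not by defect.  Emitted artifacts: phased VCF (configurable
per-genotype missingness; a configurable fraction of sites has the derived
allele as REF), a sample→population table, a 7-species outgroup state
table consistent with the true ancestral alleles up to configurable
error/absence rates, a toy GFF3 with genes flanking the planted sweeps,
and a JSON truth manifest.

Note the per-SNP resolution limit observed on these fixtures: the
EHH-family statistics peak at mid-frequency hitchhikers flanking a
near-fixed swept core rather than at the core SNP itself (whose pooled
homozygosity is degraded by sweep-borne "shoulder" mutations).  Sweep
recovery on synthetic cohorts is therefore assessed at the footprint
scale (a selective site within 50 kb of the planted SNP), which is what
the method resolves.

**What the generator does not emulate.** Real demographic histories
(growth, structured bottlenecks), gene conversion, mutation-rate and
recombination-rate heterogeneity, genotyping error other than uniform
missingness, and reference bias.  Passing tests demonstrate the statistics
and the pipeline plumbing are correct and calibrated under a neutral
Wright–Fisher null; they do not certify power or error rates on real data.

## Numerical choices

- EHH integration: trapezoid on physical distance, truncation at the first
  sub-cutoff offset with linear interpolation to the crossing; arms that
  reach the matrix edge above the cutoff are integrated to the edge and
  flagged truncated.
- Sites with pooled MAF < 0.05 are not scored (scan-tool convention;
  configurable).
- Standardization uses sample (n−1) sd; a zero-sd bin is an error naming
  the bin, never silently dropped.
- P = 0 inputs to Fisher's method are clipped to the smallest positive
  float with a warning.
- QC order is fixed: individuals with >15% missing entries are removed
  first, then sites with >10% missingness or a singleton minor allele
  (count exactly 1 after individual removal).  The order matters: a second
  pass can in principle remove further individuals under adversarial
  missingness patterns; under homogeneous missingness the filter is
  idempotent.
- r² uses pairwise-complete haplotypes; monomorphic pairs are skipped and
  counted.  The LD-decay half-maximum distance is the smallest bin upper
  edge with mean r² ≤ max/2.
- Coordinates are 1-based closed (VCF convention) internally; BED exports
  are 0-based half-open.

## Known limitations

- Fisher's method assumes independent P values; the four statistics are
  correlated (see above).
- The desk-scale classifier ceiling: with the study priors f ~ U[e, 1],
  a large share of draws are weak partial sweeps whose (H12, H2/H1) are
  uninformative at N = 500, bounding achievable hard/soft accuracy well
  below what the full-scale design could reach.  Measured on this
  generator, the Bayes-factor rule classifies held-out labelled panels at
  ~0.64 accuracy, and a k-nearest-neighbour classifier trained on the
  same (H12, H2/H1) points does no better (~0.66–0.69, also at the
  200-kb region length) — the feature plane itself saturates there at
  this scale, although the ordering signatures (hard: higher H12, lower
  H2/H1) are highly significant.
- iHS/nSL at sites whose derived allele is fixed in one population are
  undefined there (no ancestral carriers); the combination layer keeps such
  sites through the cross-population statistics.
- The forward simulator tracks a single crossover per transmitted gamete
  per generation (rL ≪ 1 in all supported configurations).
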