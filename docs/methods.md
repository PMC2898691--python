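# Methods

## The demographic model

`weedyrice` implements inference for a two-population founder model of
weed origins from a crop or wild progenitor. Forward in time:

1. A founder lineage of effective size η_p splits from the progenitor
   (constant size η_c) at time τ_s years before present; η_p is
   constrained equal to η_c, so the split itself loses no diversity.
2. At τ_f the founder lineage arrives in the new range (for U.S. weedy
   rice, after cultivated rice was introduced, so τ_f < 400 ybp) and
   passes through a bottleneck of size η_b.
3. At τ_g the population recovers instantaneously to its current size
   η_r, with no growth thereafter. τ_g is bounded by the onset of rapid
   expansion of rice cultivation (~140 years before a late-2000s sampling
   date).

Both weedy and cultivated rice are effectively annual and almost
completely selfing; the model treats the weed lineage as fully selfing by
halving the effective size of every weed epoch (η_r, η_b, η_p), which is
equivalent to running the weed's coalescent clock on 2N rather than 4N.
The progenitor is left unscaled; for wild, partially outcrossing
progenitors this is conservative, and the flag `weed_selfing=False`
removes the correction.

The competing hypotheses differ only in the prior on τ_s:

| scenario            | τ_s prior                       |
|---------------------|---------------------------------|
| `founding_us`       | τ_s = τ_f (divergence at founding) |
| `post_domestication`| τ_f < τ_s ≤ 12,000 ybp          |
| `domestication`     | τ_s = 12,000 ybp (fixed)        |
| `pre_domestication` | 12,000 ≤ τ_s ≤ 50,000 ybp       |

The `domestication` window is not pinned down by the historical record;
we fix it at the conventional 12,000 ybp onset of Asian rice
domestication and expose it as configuration.

## Units and scaling

Simulation follows Hudson's `ms` conventions: time in units of 4·N_ref
generations, sizes as ratios to a reference effective size N_ref, and a
per-locus population mutation rate θ = 4·N_ref·μ·L. N_ref is derived
from a reference per-site diversity via N_ref = θ_site/(4μ); the default
anchor is the silent-site Watterson's θ of *O. rufipogon* (7.787/kb),
whose frequency spectrum is consistent with a constant-size population.
With μ = 1×10⁻⁸ per site per generation and one-year generations this
gives N_ref ≈ 194,675. The intragenic population recombination rate ρ is
set equal to θ by default (`rho_over_theta`).

The prior on η_c is expressed as a ratio to N_ref on [0.1, 0.7],
spanning the observed ratio of crop to wild silent diversity; η_r/η_c
and η_b/η_r are uniform on (0, 1], with every size floored at one
individual.

## The coalescent simulator

Each locus is simulated on the continuous interval [0, 1) under the
ancestral recombination graph: lineages carry sorted ancestral segments
tagged with the set of sampled haplotypes they subtend (a bitmask);
coalescence in a population of relative size x occurs at rate k(k−1)/x,
recombination at rate ρ times the ancestral span of each lineage, with
the breakpoint uniform in the span; segments that reach their MRCA are
dropped. Demographic events (instantaneous size changes and the backward
merge of the weed into the progenitor at τ_s) interrupt the exponential
waiting times. Mutations are laid down afterwards under the
infinite-sites model at rate θ per unit of (branch length × ancestral
material), by sampling branch records proportional to their mutational
opportunity. Identical seeds give bit-identical output, and per-locus
streams are derived from (master seed, locus index) so extending a panel
never reshuffles earlier loci.

Rendering to sequence maps continuous positions to integer columns;
collisions at the same column are re-drawn uniformly among free columns.
This preserves allele counts exactly but not inter-site distances at
single-base resolution.

Calibration (tested): at constant size, mean S per locus equals
θ·L·a_{n−1} and mean pairwise difference equals θ·L within Monte-Carlo
error, and the mean of Tajima's D is near zero. The mean D of the
neutral coalescent at these sample sizes is genuinely slightly negative
(about −0.06 at n=10, θ≈3.9; an independent simulator reproduces the
same value), which the calibration band accommodates.

## Summary statistics

All estimators run on a biallelic 0/1 matrix built per locus by dropping
any column touching an alignment gap, dropping columns with three or
more alleles among the targeted groups (alleles confined to outgroup
samples do not remove a site), and coding the major allele among
targeted samples as 0 (alphabetical tie-break). Heterozygous IUPAC calls
in this haploid setting default to missing; "first base" and seeded
"random base" policies are available. Missing data are handled per site:
Watterson's θ weights each segregating site by 1/a_{n−1} of its own
non-missing sample size, and π uses observed pairs only. Per-kb values
divide by the locus's non-indel column count of the requested site class
("silent" pools synonymous and noncoding).

F_st is the Weir–Cockerham (1984) two-population estimator on haploid
allele counts with three fixed aggregation rules: SNPs whose pooled
minor-allele count is one are dropped; negative per-SNP estimates are
set to zero before the per-locus mean; loci with no retained SNP enter
the grand mean (and median) as zeros. Note the zero-clamping makes the
null expectation of the aggregated statistic slightly positive — the
unclamped per-SNP mean is the right quantity for testing "no
differentiation".

The rejection sampler compares eight statistics pooled over all loci:
combined-sample π per kb; S within the weed, within the progenitor, and
in the pooled sample; and the fixed / private-weed / private-progenitor /
shared partition of sites. The published description enumerates seven;
we take the eighth as S in the pooled sample and keep the slot
configurable. Statistics are computed on all site classes by default
(a silent-only switch exists).

## Rejection ABC

A discrete grid covers the three timing parameters and the η_c ratio
(default five points per axis, endpoints included, invalid orderings
excluded and counted); the two size ratios are drawn continuously.
Simulations cycle deterministically through grid cells. Summary vectors
are first passed through the variance-stabilizing log(1+x) transform —
the statistics are pooled counts whose sampling noise grows with their
mean, and without the transform a contrast like "3 vs 12 weed
segregating sites" is swamped by the spread of the progenitor-side
counts (a raw-scale option remains available). Transformed vectors are
standardized by the per-statistic median absolute deviation of a
cross-scenario pooled pilot (zero-spread statistics fall back to scale
1 with a warning), and a draw is accepted when its standardized
Euclidean distance to the observed vector is within the tolerance. The
approximate likelihood of a scenario is its acceptance proportion; the
standardization and threshold are shared across scenarios precisely so
these proportions are comparable. Tolerance can be given as an absolute
standardized distance or as a pooled-table quantile ("pooled-quantile"
mode), which derives one shared absolute threshold; a per-scenario
quantile would force equal acceptance rates and destroy the comparison.

Tolerance matters: the acceptance proportion only approximates the
likelihood as the tolerance shrinks, and a coarse tolerance biases the
comparison toward the scenario with the wider prior predictive. In our
pilot experiments recovery of a founding-time truth improved
monotonically as the acceptance fraction fell from 2% to 0.1% on raw
statistics, and became insensitive to the tolerance once the log
transform was applied; the recovery experiment uses a 0.2% pooled
acceptance fraction on transformed statistics.
Posterior densities are acceptance histograms (integrating to one
whenever anything was accepted), and the bottleneck surface is the 2-D
acceptance density over (η_r/η_c, bottleneck intensity), intensity being
the percent decline 100·(1 − η_b/η_r) clipped to [0, 100].

The reference table depends only on priors and simulation settings,
never on observed data, so one table is reused across many observed
panels; this is what makes the paired recovery experiment (40 panels
against 10,000 simulations per scenario) tractable on one CPU.

## Synthetic data

The generator produces pseudo-observed panels under named presets that
encode the qualitative findings for the two main U.S. weed groups —
illustrative parameter sets, not estimates:

* `SH` (straw hull / *indica*): η_c = 0.28·N_ref, η_r/η_c = 0.06,
  η_b/η_r = 0.01 (a 99% decline), τ_s = τ_f = 200, τ_g = 100; 24 weed
  and 22 progenitor haplotypes.
* `BHA1` (black hull awned / *aus*): η_c = 0.18·N_ref, η_r/η_c = 0.2,
  η_b/η_r = 0.3, τ_s = 10,000, τ_f = 200, τ_g = 100; 15 and 7
  haplotypes.

The default panel is 48 loci of 500 bp (the study's panel spanned
400–921 bp; a uniform 500 bp keeps per-locus θ constant without changing
any pooled statistic's interpretation). What the generator emulates:
nested weed diversity, near-complete selfing via haploid sampling, free
recombination between loci, ρ = θ within loci, and cytotype panels drawn
from given frequencies. What it does not: sequencing error, alignment
gaps, heterozygous residual calls, linkage between loci, migration after
the split, selection, and admixed/hybrid genomes — so passing tests
validate the inference machinery, not robustness to those features of
real data.

## Scaled-down experiment sizes

Full-size runs (~850,000 simulations per scenario) are configuration the
package honors; the bundled experiments use sizes chosen for a single
CPU: calibration with 2,000 replicate panels of 48 loci; the recovery
experiment with 32 loci × 500 bp, 16+16 haplotypes and 10,000
simulations per scenario for the two contrasted scenarios (founding_us
vs pre_domestication — the pair the hypotheses most need to separate);
the surface experiment with 16 loci, 12+12 and a 5% acceptance fraction
(surfaces want many accepted draws; classification wants few).
`scripts/acceptance.py` reports the same quantities at further-reduced
sizes noted in its output.

## Numerical notes and limitations

* Exact rational arithmetic for acceptance proportions; everything else
  is float64.
* Tajima's D is reported as NaN for S = 0 or fewer than four haplotypes;
  with missing data its variance constants use the rounded mean per-site
  sample size.
* The unbiased pairwise-difference estimator of π (pairs denominator
  n(n−1)/2) is used throughout; it is invariant to how labels partition
  a pooled sample but not to duplicating samples.
* Single-population F_st, >2-population models, migration after τ_s,
  gene conversion and regression-adjusted ABC are out of scope.
* IMa-style mutation-scaled estimates can be converted to natural units
  with `rescale_estimate` (N = θ̂/4u; years = t̂/u × generation time);
  the MCMC machinery itself is not reimplemented.
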