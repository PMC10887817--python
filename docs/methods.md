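# Methods

## Setting

`panelkit` targets the analysis regime of targeted SNP-seq panels: a few
hundred biallelic markers chosen for high information content (MAF close
to 0.5), amplicon-sequenced at very high depth (~1000×) across a
germplasm collection of inbred lines structured into populations and
subpopulations. In this regime genotype calls are nearly error-free,
heterozygosity is rare (inbreeding coefficients ≈ 0.94–0.98), and the
interesting quantities are marker informativeness, group differentiation
and minimal discriminating marker subsets.

## Genotype calling

Calls are made directly from allele read frequencies. For a count map at
one (sample, locus): the two highest-count alleles are major and minor
(ties broken alphabetically — label-only, since genotypes are unordered
pairs); frequencies are computed over **all** observed alleles, so
contamination or a third allele depresses both top frequencies. The call
is

* homozygous major if major frequency > 0.7 (strict);
* heterozygous (major, minor) if both top frequencies > 0.35 (strict);
* missing otherwise — including the ambiguous zone (e.g. 0.65/0.30) that
  satisfies neither rule, and any record below the depth floor.

Only the two positive rules are defined by the calling scheme; mapping
the left-over zone to missing is a deliberate refusal to invent a call.
The depth floor defaults to 20 reads: at 1000× mean depth it is nearly
inert, but it guards against amplicon dropout tails. Both thresholds and
the floor are configurable (`CallThresholds`).

The partition {hom, het, missing} is exhaustive and exclusive and the
rule is scale-invariant in the counts; both properties are enforced by
exhaustive enumeration over count grids in the test suite, along with a
brute-force check that growing the major count can never flip a call to
the opposite homozygote.

## Panel QC ("perfect SNPs")

Five filters, strict comparisons: MAF > 0.4, missing rate < 0.2,
observed heterozygosity < 0.2, clean 100-bp flanks, exactly two alleles.
Conventions:

* MAF at filter time is computed from genotype calls (two allele
  observations per called diploid), since read-level frequencies are not
  retained post-calling.
* The flank window is boundary-inclusive: a known variant at exactly
  `flank_bp` fails the locus. Flank checking consults a genome-wide
  variant-position table, not just panel candidates.
* The heterozygosity filter is the per-locus observed heterozygote
  fraction — the only per-locus heterozygosity available at filter time.

Filters are evaluated independently (hence order-independent) and the
report records every failure reason per locus.

## Diversity statistics

For allele frequencies p at a locus: GD = 1 − Σpᵢ² (Nei), PIC = 1 − Σpᵢ²
− Σᵢ<ⱼ2pᵢ²pⱼ² (Botstein), Ho = heterozygous fraction of called
genotypes, MAF = second-highest allele frequency (the general
multi-allelic convention, although QC-passed panels are biallelic), and
F = 1 − Ho/GD. Choices:

* GD is reported without small-sample correction by default; the
  2n/(2n−1) unbiased variant is available as an option.
* Undefined statistics are reported as NaN, never 0 — in particular F at
  monomorphic loci. "Count of loci with F = 1" therefore counts exactly
  the polymorphic loci with zero heterozygotes.
* Group-level F uses the ratio of means, 1 − mean(Ho)/mean(GD), over the
  group's polymorphic loci; mean-of-ratios explodes on near-monomorphic
  loci. Comparisons against externally computed group F should check the
  estimator first.
* A marker is polymorphic within a group iff ≥ 2 alleles are observed
  among the group's non-missing calls.

PIC < GD for every polymorphic locus and PIC ≤ 0.375 for biallelic loci
(maximum at p = 0.5) are enforced as properties.

## Differentiation

**Fst.** Weir & Cockerham's (1984) θ: per locus and allele, variance
components a (among populations), b (among individuals within), c
(within individuals) from sample sizes, allele frequencies and observed
heterozygote frequencies; multi-locus θ = Σa / Σ(a+b+c) over loci with
defined components (loci monomorphic across the pair, or with an empty
group, are skipped). Estimates are reported unclamped; θ slightly below
zero is the expected behaviour of the estimator near zero
differentiation. θ is validated by parameter recovery on Balding–Nichols
simulations (recovering a simulated divergence of 0.30 within ±0.05 with
200 loci and 60+60 inbred samples), by the fixation limit (θ = 1) and by
the panmictic null (|θ| < 0.02).

**AMOVA.** Allelic variance is partitioned across four nested strata —
between populations, between subpopulations within populations, between
samples within subpopulations, within samples — treating each diploid as
two allele draws with 0/1 distance per locus mismatch. Because the
distance is 0/1, every within-group sum of squares reduces to allele
counts: SS = Σ_loci (n/2)(1 − Σp²) for a group with n called alleles, so
no phase assignment is needed (the within-samples stratum reduces to
half the heterozygote count). Stratum SS are differences of these
within-partition sums; degrees of freedom are P−1, S−P, N−S, N (total
2N−1). Variance components solve the linear system equating observed to
expected SS, with expected-SS coefficients computed exactly for the
unbalanced nested design (the generic A − Σ_g Σ_{C⊆g} n_C²/n_g formula
per component and partition); strata with zero df (e.g. a collapsed
subpopulation level) are dropped and their component fixed at zero,
leaving the total variance unchanged. Negative components are retained
as estimated and logged. Missing calls are excluded per locus from the
SS while design coefficients use full sample sizes — exact when
missingness is zero, and a very mild approximation at the <2% rates the
pipeline targets. Percentage rows are components over their sum × 100.

The AMOVA implementation is cross-checked against a brute-force pairwise
allele-distance oracle and, on a balanced 2×2×2 design, against the
closed-form textbook EMS coefficients.

## Trees, distances, PCA

The differential-genotype matrix counts, per sample pair, loci where both
calls are present and the unordered genotypes differ; missing calls are
null (excluded from numerator and denominator). The NJ input is the
proportion n_diff/n_comparable, which removes the bias of unequal
comparable counts; as a per-pair Hamming fraction over per-pair locus
sets it need not satisfy the triangle inequality, which NJ does not
require. NJ is the standard Saitou–Nei agglomeration with deterministic
tie-breaking (lexicographic by the joined subtrees' smallest leaf label)
and negative branch lengths clamped to zero with the deficit moved to
the sister edge, preserving each join's summed length. Correctness is
validated by exact topology recovery (RF = 0, via an independent tree
library) on distances generated from random additive trees.

PCA codes biallelic loci as panel-wide-minor-allele dosage (0/1/2) and
multi-allelic loci one-hot per allele; missing cells are mean-imputed per
column (defensible at <2% missingness, increasingly distorting beyond
that); columns are centred, the covariance eigendecomposed via SVD, and
component signs fixed by making each component's largest-magnitude
loading positive.

## Core-SNP sets and core lines

Minimal discriminating subsets are greedy set cover over unresolved
sample pairs: select the locus resolving the most currently-unresolved
pairs; ties by higher GD, then panel order (a fixed rule, so the output
is reproducible). Missing genotypes never resolve a pair, but count as a
distinct symbol when counting distinct multilocus fingerprints (a
fingerprint string must be printable). The greedy stops when no locus
adds a pair; pairs unresolvable by the entire panel (duplicate
fingerprints) are reported explicitly. On instances small enough for
exhaustive subset search the greedy is empirically within one locus of
the true minimum ≥90% of the time, and always resolves everything the
panel can.

Core lines are each subpopulation's most central members: ranked by
ascending mean pairwise difference count to the rest of the group (ties
by sample id), taking the top round-half-up(fraction × n) with a floor
of one line per group. Note that at fraction 0.10 a group of 11 yields
one line, and collections with group sizes like (183, 170, 120, 11)
yield 48 — "top 10%" under any single rounding rule; published counts
may differ by one from per-group arithmetic.

## Synthetic data

The generator produces the study conditions used throughout the tests:

* ancestral frequencies ~ Uniform(0.40, 0.50) on a random allele
  orientation (the high-MAF band panel QC selects for);
* per-subpopulation frequencies from the Balding–Nichols model
  Beta(p(1−F)/F, (1−p)(1−F)/F), giving E[(p_s−p)²] = F·p(1−p) — the
  moment identity is verified at fixed seeds;
* genotypes with partial selfing: autozygous with probability
  `selfing_f`, else two independent draws; expected Ho =
  (1−selfing_f)·2p(1−p), so selfing 0.97 gives panel Ho ≈ 0.01;
* reads: negative-binomial depth (mean 1000, dispersion 10), multinomial
  allele counts with error rate 0.005 spread over the other three
  nucleotides, optional record dropout.

The canonical fixture has four subpopulations of 46/42/30/8 lines (a
quarter-scale version of a realistic fruit-shape-structured collection)
and 100 loci, with graded divergences (0.66, 0.21, 0.125, 0.52) chosen so
estimated pairwise Fst spans roughly 0.17–0.62 and the most-drifted
subpopulation shows the lowest internal diversity. Loci are simulated
independently: the generator makes no attempt at linkage, allele-specific
amplification bias, index hopping, or batch effects, so passing tests
demonstrate correctness of the estimators under the model, not robustness
to those real-data artefacts.

All generator output is bit-reproducible from (config, seed); sub-streams
are keyed per stage so adding loci to one stage does not perturb another.

## Numerical and interface conventions

* Coordinates are 1-based inclusive (VCF convention) everywhere.
* Genotypes are unordered pairs; heterozygote codes normalise to sorted
  order on ingest ("GA" ≡ "AG"); missing is "--".
* Frequencies must sum to 1 within 1e-6 where supplied directly.
* All result tables have deterministic layouts; the run manifest records
  version, config, seed and input checksums but no timestamps, so
  identical runs are byte-identical.
* A rerun into an output directory whose manifest matches the current
  config and input checksums is skipped wholesale; any change reruns the
  full pipeline (per-stage caching was judged not worth the complexity at
  these problem sizes).

## Problem sizes

Test-suite simulations are deliberately small — 100–200 loci,
60–126 samples — which keeps the full suite around half a minute while
leaving every estimator's tolerance comfortably testable; the acceptance
script uses the same canonical conditions.

## Known limitations

* AMOVA missing-data handling (full-size design coefficients) is
  approximate under heavy missingness; the intended regime is <2%.
* No significance testing (permutation p-values) for Fst or AMOVA.
* No LD, no haplotype statistics; loci are treated as independent.
* Exact minimum core-set search is exponential and only used as a test
  oracle; production output is the greedy (with its well-known ln-factor
  worst case, rarely realised on panel data).
* PIC for a biallelic locus cannot exceed 0.375; panels reporting higher
  per-locus PIC either carry extra alleles or use a different PIC
  variant.
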