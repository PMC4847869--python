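# Methods

This note records the models implemented in `indelsweep`, the
assumptions and parameter choices behind them, and what the synthetic
data used by the test suite does and does not establish about behavior
on real data.

## Data model

Input panels are haploid consensus sequences (one chromosome per
isofemale line) in a rectangular multiple alignment over
`{A,C,G,T,-,N}`. Coordinates are 1-based with inclusive intervals.
Nucleotide statistics use site-wise deletion: any column containing a
gap or `N` is dropped, matching the convention of desktop
population-genetics tools. Gap-containing columns that form a run of
two or more consecutive columns with the same set of gapped sequences
are classified as an `indel` event (collapsed to one event per run);
isolated gap columns and `N` columns are `excluded`. A sequence is a
deletion *carrier* when at least 90% of the event's span is gapped —
the margin tolerates ragged alignment edges while refusing to
classify silently ambiguous sequences (10–90% gapped raises an
error naming the sequence).

Alleles are polarized by majority vote across outgroup sequences
aligned to the same columns; ties and missing outgroup data leave a
site unpolarized, and unpolarized sites fall back to folded (minor
allele) treatment downstream.

## Diversity statistics

*S* counts columns with two or more states among usable columns.
Watterson's estimator is θ_W = S/(a₁·L_eff) with a₁ = Σ_{i<n} 1/i,
reported per 100 sites; π is the mean pairwise difference per usable
site × 100. Tajima's D = (π_locus − S/a₁)/√(e₁S + e₂S(S−1)) with the
standard coefficients; it is undefined (reported missing) at S = 0.
Its significance is assessed by conditional-on-S coalescent
simulation — constant-size genealogies with exactly S mutations,
two-sided empirical p — rather than the beta approximation, since the
package owns a simulator anyway.

F_st between haploid panels is the Hudson–Slatkin–Maddison form
1 − H_w/H_b, where H_w averages the two within-population mean
pairwise differences and H_b is the mean cross-population difference.
Negative estimates are reported as computed, not clamped, so that
window averages remain unbiased. Sliding windows default to 500
columns with a 250-column step (1000 bp for the CLR scan grid);
per-window statistics are normalized by that window's usable column
count, and windows with no usable columns are reported missing.

## Coalescent simulator

Time is measured in units of 4N₀ generations and positions on [0, 1),
the ms convention, so published bottleneck parameters transcribe
directly. For k lineages the coalescence rate is k(k−1)/ρ_size(t)
under a piecewise-constant size history ρ_size = N(t)/N₀; epoch
boundaries are handled by the standard redraw-at-boundary
construction. Recombination follows Hudson's ancestral recombination
graph: each lineage recombines at rate ρ·(span of its ancestral
material), the breakpoint uniform on that span; coalescing lineages
merge segment-wise, each overlapping sub-interval receiving a fresh
parent node, and an interval is retired once its marginal tree reaches
all n samples. The full ARG (no sequential-Markov approximation) is
adequate for a 6-kb locus where ρ is small.

Mutations are placed in two modes. θ-mode draws
Poisson(θ · Σ_intervals width × tree length) mutations — branch
lengths are in 4N₀ units, so E[S] = θ·a₁(n) under constant size — with
the branch chosen proportionally to length and the position uniform
within the interval. Fixed-S mode places exactly S mutations the same
way (Hudson's conditional simulation), which is how all
conditional-on-S tests are run. Both modes are infinite-sites: every
emitted column segregates in the full sample. The simulator is
cross-checked in the test suite against msprime on matched scalings.

### Demographic models

Three named out-of-Africa bottleneck configurations ship as editable
YAML ("duchen", "werzner", "thornton-andolfatto"), anchored only by
their bottleneck ages (~19, ~16 and ~13 thousand years, at 10
generations/year and N₀ = 10⁶, i.e. onset times 0.0475/0.04/0.0325 in
4N₀ units). Their severities and ancestral sizes are **placeholders**
(flagged `placeholder: true`): the original parameter sets are not
transcribed here, so these configs support property and directional
tests, not reproduction of published p-values. Users with the full
published parameters can replace the epoch lists directly.

## Hudson's haplotype test

The observation is (n, S, i, p): a subset of i sequences (the indel
carriers) holding p of the S segregating sites. The null probability
that *some* subset of size i carries ≤ p segregating sites is
estimated by simulating genealogies under the chosen demography,
placing exactly S mutations, and computing the minimum over all
C(n, i) subsets of within-subset segregating sites. The minimum is
exact via a subtree dynamic program: f(v, k) is the cheapest choice of
k tips inside v's subtree, where a child contributing 0 < k' < i tips
pays its stem's mutation count; the answer is f(root, i). The DP is
validated against exhaustive enumeration for n ≤ 8. The test is
one-sided (small p-values = excess haplotype homogeneity), and the
criterion is existence of *any* sufficiently homogeneous subset — the
carrier class is not labeled in simulations. Recombination is not
offered for this test: the subset minimum is defined on a single
marginal tree.

A directional caveat found while validating: whether a bottleneck
inflates the p-value relative to constant size depends on its
severity and timing. A recent moderate bottleneck leaves deep splits
intact and makes homogeneous subsets likelier (p rises); an extreme
crash produces star-like genealogies and reverses the sign. The
shipped bottleneck configurations are in the former regime.

## Composite likelihood ratio sweep scan

The background SFS is empirical, over derived-count classes 0..n with
the invariant classes included (they carry real likelihood weight and
increase power); empty classes receive one pseudo-count before
normalization to avoid −∞ log-likelihoods on small backgrounds. At
distance d from a putative sweep site a lineage escapes the sweep with
probability p_e = 1 − e^{−αd}; α (per bp) absorbs the regional
recombination rate and selection strength, leaving one free unit. The
post-sweep spectrum marginalizes B ~ Binomial(n, p_e) escaping
lineages: the background is hypergeometrically down-sampled to B + 1
lineages (the escapees plus the swept class's single ancestor), and
the ancestor's allele is expanded back to n − B copies. The transform
conserves probability mass to ≤ 10⁻⁹ and reduces to the background as
p_e → 1; at p_e = 0 all mass sits on the invariant classes {0, n}.

The scan statistic at a grid point (default spacing 1000 bp) is
Λ = 2(sup_α Σ_sites log P(count | sweep) − Σ_sites log P(count | bg)),
with invariant sites included in both sums. Since the background is
the α → ∞ limit of the sweep model, Λ ≥ 0. α is searched on 50
log-spaced points over 10⁻⁶–10⁻¹ per bp and refined by golden section
on log α.

Numerical choices: p_e is discretized onto 128 equispaced values and
the transformed spectra precomputed once, making per-site likelihoods
table lookups; in calibration replicates the invariant sites are
represented as weighted pseudo-sites on a 50-bp lattice. Both choices
keep a 1000-replicate calibration to well under a minute per scan
configuration on one CPU and change Λ by less than the Monte Carlo
noise of the calibration itself. Unpolarized data can be scanned in
folded mode (fold after the transform); folded and unfolded scans
agree exactly on symmetric spectra.

Significance thresholds are simulation-calibrated: neutral loci are
simulated under the chosen demography, scanned against the *same*
empirical background used for the data scan, and the 95th percentile
of the per-replicate maximum Λ is the 5% threshold. The test suite
calibrates at 1000 replicates (reduced from the historical 10,000-
replicate convention, a package choice balancing Monte Carlo error on
the 95th percentile against runtime) and verifies that fresh neutral
replicates are rejected at ~5%.

A modeling note: synthetic sweep data drawn i.i.d. from the sweep
spectrum itself (the generator's "sweep" scenario) carries no
genealogical correlation between sites, whereas calibration
replicates do; the calibrated threshold is therefore conservative for
model-consistent data, and scan power in the tests (≥ 80% at strong
intensity, α ≈ 3×10⁻⁴/bp over a 6-kb locus) should be read as power
against that conservative threshold.

## Pooled-read indel frequencies

Reads are semi-globally aligned (match +1, mismatch −1, gap open −3,
gap extend −1, free reference end gaps) to both reference haplotypes.
A read is informative only if it crosses the indel junction with at
least `min_flank` (default 5) aligned bases on each side; the junction
coordinate is the deleted segment's left edge on *both* references, so
the capture window is identical for the two alleles and the
proportion-of-informative-reads estimator is unbiased — a property the
tests verify against generator truth. Reads covering the junction but
tying in score are counted as dropped (reported, excluded from the
denominator). The deletion frequency is del/(del + anc) with a
binomial 95% CI on the probit scale: z₀ = Φ⁻¹(p̂), delta-method
standard error √(p̂q̂/n)/φ(z₀), bounds Φ(z₀ ± 1.96·SE). At k = 0 or
k = n the probit transform degenerates and exact Clopper–Pearson
boundary intervals are used instead; this hybrid reproduces every
printed interval of the bundled surveys at two decimals.

## Clines and linkage disequilibrium

Cline fits are ordinary least squares of per-population deletion
frequency on latitude — each population one unweighted point (an
allele-count-weighted option exists but is off by default, matching
the unweighted convention of the original analysis); the correlation
is Pearson's r and the slope's two-sided p comes from t = r√(n−2)/√(1−r²)
with n − 2 degrees of freedom. Isofemale lines contribute two alleles
each, heterozygous lines one of each state. Two-population
comparisons use Fisher's exact test (two-sided, hypergeometric
enumeration) on allele counts. LD between biallelic SNPs is
r² = D²/(p₁q₁p₂q₂) from haploid haplotype counts with a Fisher exact
test per pair on the 2×2 haplotype table; singletons are excluded by
default and p-values are reported raw (a Bonferroni flag exists but
no correction is applied by default).

## Synthetic data: scope of the evidence

The generators emulate the statistical structure the estimators
assume: neutral coalescent alignments (with optional bottlenecks and
recombination), sweep site tables drawn from the scan's own spectrum,
logistic clines with binomial allele sampling, and uniform-start,
uniform-error reads over an indel junction. They do **not** emulate
alignment errors, indel-adjacent mis-alignment, base-quality
structure, linked selection other than the single modeled sweep, or
spatial population structure beyond a marginal logistic cline.
Passing tests therefore establish internal consistency and
correctness of the mathematics at the study's design scale (n = 12
haplotypes, 6-kb locus, 1-kb grid, 10/2 carrier split), not
robustness to those real-data pathologies.

Default scales used by the test suite: coalescent moment checks at
10⁴ replicates; haplotype-test enumeration oracle at 200 random trees
(n ≤ 8); CLR calibration and its rejection self-test at 1000
replicates each; CI coverage at 10⁴ binomial draws per (p, n)
combination. Seeds are fixed throughout; every Monte Carlo assertion
uses a tolerance derived from its own standard error.

## Known limitations

- The bundled demographic configurations are placeholders (above);
  quantities that depend on the exact bottleneck parameters —
  notably haplotype-test p-values — are not comparable to published
  values until real parameter sets are substituted.
- The haplotype test does not support recombination within the locus.
- The CLR scan assumes a single constant per-bp recombination rate
  folded into α and a single sweep; recurrent sweeps and B-value-style
  heterogeneity are out of scope.
- Pool-read classification treats read pairs as independent reads and
  ignores base qualities.
- The scan requires all sites to share the background's sample size;
  sites with missing haplotypes must be dropped or imputed upstream.
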