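# Methods

## Informativeness for assignment

For a biallelic SNP with allele-1 frequencies `p_1 … p_K` across the K
source populations, the informativeness for assignment is

    In = Σ_{j∈{1,2}} ( −p̄_j ln p̄_j + Σ_i (p_ij / K) ln p_ij ),

where `p̄_j` is the unweighted mean of allele-`j` frequencies over the K
populations and `0·ln 0 := 0` (implemented with `scipy.special.xlogy`).
Natural logarithms are used; any base gives the same marker ranking.  The
mean is unweighted — the "average population" gives every source equal
standing regardless of reference sample size; sample sizes enter only the
heterogeneity test.  Frequencies are not clamped here: exact 0/1 values are
handled by the `0·ln 0` rule, and floating-point round-off on exact-tie
inputs is floored at 0.  For biallelic markers `0 ≤ In ≤ ln 2`, with
equality at 0 iff all populations share a frequency.

## Subgroup heterogeneity screen

When a source population pools several cohorts (subgroups), a marker whose
frequency differs among those subgroups is suspect: its informativeness may
reflect within-source structure rather than between-source divergence.  For
every source with ≥ 2 subgroups the screen forms the 2 × S allele-count
table (counts = frequency × observed allele copies) and computes a Pearson
chi-squared statistic with df = S − 1 (the p-value via `scipy.stats.chi2`);
a SNP is discarded when any source tests below `alpha` (default 0.05,
configurable — no canonical value exists).  Degenerate tables (monomorphic
across subgroups, or fewer than two subgroups with data) are skipped and the
SNP kept.  The filter is **off by default**: empirically, discarding
heterogeneous SNPs removes markers that also separate the sources and lowers
panel accuracy, so it is an opt-in diagnostic rather than a standard step.

## Greedy selection

Stage 1 takes `round(proportion_multi × n_aims)` markers (half away from
zero) in decreasing multi-population `In` order.  Stage 2 repeats until the
panel is full: find the population pair(s) with the smallest running `In`
total (all totals start at zero, so initially all pairs are tied); among
tied pairs, locate each pair's best acceptable unselected marker by that
pair's `In`; accept the (pair, marker) combination with the highest `In`;
credit the marker's pairwise `In` to that pair's total.  Stage-1 picks do
not feed pair totals — they precede balancing, and crediting a multi-
population score to a single pair would be ill-defined.

Deterministic tie-breaks beyond the pair rule: markers tied on `In` resolve
by (chromosome, position, snp_id) ascending; pairs still tied resolve in
canonical (lexicographic) pair order.  Identical inputs therefore always
produce byte-identical panels, and with `proportion_multi = 0` and fixed
constraints a panel of size m is a prefix of any larger panel.

Acceptance checks against the panel so far: not already selected; genotypic
r² ≤ `ld_r2_max` (default 0.2, configurable — no canonical threshold
exists) against every selected marker, where r² is the squared Pearson
correlation of dosage vectors over individuals with both genotypes observed
and an undefined r² (fewer than two complete pairs, or zero variance)
passes; distance > `min_distance_bp` (default 100 000) from every selected
marker on the same chromosome.  LD is computed in the admixed study cohort's
genotypes — the population in which the panel will be used and in which
admixture LD matters.  Because the panel only grows, a failed candidate can
never pass later; rejections are cached as permanent, which makes the
scan-from-pointer implementation exact, not approximate.  A pair whose
candidates are exhausted is marked starved and excluded from the minimum-
total search; if all pairs starve the partial panel is returned with a
warning.

Sliding-window LD pruning (for genome-wide baselines) uses a 50-SNP window
shifted by 10 SNPs within each chromosome; whenever a kept pair within the
window exceeds the r² threshold the later-positioned marker is removed.

## Supervised ancestry estimation

Given fixed reference allele-1 frequencies F (clamped to
[1e−6, 1 − 1e−6] so the likelihood never evaluates log 0 at fixed
reference alleles), each individual's ancestry vector q maximizes the
binomial-mixture likelihood with per-marker success probability
`p_m = Σ_k q_k f_mk`.  EM from the uniform start `q = 1/K` runs until the
relative log-likelihood change falls below 1e−7 (default) or 1000
iterations; missing genotypes are skipped; the log-likelihood is
non-decreasing every iteration (asserted in tests).  Boundary estimates
(q_k = 0 or 1) are allowed.  Individuals with no observed genotypes get a
missing row and a warning.

This is a deliberate substitution for unsupervised clustering of the
combined reference-plus-admixed data: holding F fixed makes estimation
deterministic, independent across individuals, and desk-scale, while the
pipeline keeps the labeling step an unsupervised run would need — clusters
are matched to sources by largest mean proportion among reference
individuals, resolved as an optimal one-to-one assignment
(`scipy.optimize.linear_sum_assignment`) so conflicting argmaxes cannot
produce a many-to-one labeling.  Supervised and unsupervised estimates are
not claimed to coincide numerically.

Panel evaluation reports per-ancestry Pearson correlation and RMSE between
two sets of proportions.  A constant column makes the correlation undefined;
it is flagged, never fabricated (the constancy test is exact equality of all
values, since a variance threshold would misread float noise on a constant
column).  The permutation protocol draws seeded random sub-cohorts without
replacement and recomputes the per-ancestry correlation per draw; because
supervised estimates are independent across individuals, proportions are
fitted once on the full cohort and sliced per draw — mathematically
identical to refitting each subset, and much cheaper.

## Synthetic data

The generator emulates the study design the selector is meant for: K source
populations diverged from a common ancestor and an admixed cohort formed
from them.

* Ancestral frequencies ~ Uniform(0.05, 0.95) i.i.d. per SNP.
* Population frequencies follow Balding-Nichols drift:
  Beta(p(1−F)/F, (1−p)(1−F)/F), mean p, variance F·p(1−p).  Default drift
  (0.20, 0.15, 0.12, 0.10, 0.08) gives strictly ordered pairwise
  divergences, expected pairwise Fst ≈ (F_a + F_b)/2 under the star
  phylogeny.
* Marker maps place SNPs uniformly at random across 22 autosomes with
  length-proportional counts, so inter-marker spacing matches a genome-wide
  chip at the chosen density and the distance constraint binds as it would
  in practice.
* Reference individuals: dosage ~ Binomial(2, f).
* Admixed individuals: q ~ Dirichlet(3.1, 2.6, 1.8, 1.2, 0.7) by default —
  median proportions ≈ 0.31/0.26/0.18/0.12/0.07, the profile of the
  five-way admixed Cape Town population, with concentration total ≈ 9.4
  giving realistic inter-individual spread; each allele copy draws its
  ancestral population from q, then its allele from that population's
  frequency.

What the simulator does **not** produce: linkage disequilibrium within
sources (sites are independent given the frequencies; a helper injects
exact-duplicate markers to exercise the r² check), shared drift topology
(star phylogeny only), recombination, admixture LD, selection, sex-biased
admixture, or genotyping error.  Passing end-to-end tests therefore shows
the selector and estimator behave correctly under the declared model, not
that a real cohort's LD structure or reference-panel misspecification is
handled.

## Problem sizes and numerical choices

The reference validation scenario runs 20 000 SNPs, five sources at the
default drift, 40 reference individuals per source and 200 admixed
individuals — large enough for stable correlations, small enough for a
desk-scale run.  With these conditions a 96-marker panel recovers the three
major ancestry components at r ≈ 0.8–0.86 against truth, accuracy grows
with panel size, and the gain beyond ~100 markers is visibly smaller than
before it, which is the classic cost/benefit knee for panels of this kind.
Sub-seeds for the map, frequencies, reference and admixed draws are spawned
from the single run seed (`numpy.random.SeedSequence`), so components are
independent but jointly reproducible.

Other numeric details: panel files are written with fixed column order and
`%.10g` floats so re-reads are byte-stable; allele harmonization across
datasets accepts swapped allele records (complementing frequencies/dosages)
but never attempts strand flips, and drops strand-ambiguous A/T and C/G
mismatches as undecidable; heterogeneity counts are used as real-valued
expected counts rather than rounded integers.

## Known limitations

* The LD source for the acceptance check is a configuration choice
  (`genotypes` passed to `select_aims`); panels built without genotypes skip
  the r² check entirely.
* The heterogeneity screen uses the asymptotic chi-squared distribution;
  with very small subgroup counts an exact test would be preferable
  (deliberately out of scope).
* Supervised estimation inherits reference-panel bias: misspecified source
  frequencies shift ancestry estimates, which no amount of marker selection
  fixes.
* Binary PLINK (`.bed`) input is not parsed; convert to the text dialects
  upstream.
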