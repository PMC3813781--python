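# Methods

`agenet` analyses a two-condition ageing RNA-seq time course: gene-level
read counts for a control and a treated population, each sampled at 1, 5,
10 and 20 days with 3/3/3/2 replicates (22 samples). This note records
the statistical models, the defaults and why they were chosen, what the
synthetic-data generator does and does not emulate, and the numerical
conventions.

## Normalization and expression scales

Counts are converted to RPKM, `1e9 * count / (length_bp * sample_total)`,
where the sample total is the column sum of assigned gene counts — the
only depth measure available downstream of counting, and proportional to
the mapped-read total. Totals are taken from the *unfiltered* matrix so
filtering choices do not change the scale. Profile-based stages (MDS,
monotony, permutation tests, all networks) run on `log2(RPKM + 1)`; the
pseudo-count of 1 keeps zeros finite and is negligible for expressed
genes. Differential expression runs on raw counts with median-of-ratios
size factors (geometric mean rescaled to 1), computed from the genes
with nonzero counts in every sample.

Two gene universes coexist, as is usual for this kind of study: DE
testing uses the genes with at least `min_count = 100` reads in every
sample (low counts make exact tests unstable); temporal and network
stages use the genes with nonzero counts in both conditions.

## Differential expression

Each age level is tested separately. The test is a conditional
negative-binomial exact test: per gene, the control and treated group
sums are modelled as NB with means proportional to the groups' summed
size factors and dispersion `phi / n_group` (a sum of n i.i.d. NB(mu,
phi) variables is NB(n*mu, phi/n)); conditioning on the pooled total,
the p-value adds up the probabilities of all splits no more likely than
the observed one. Ties count toward the tail (conservative), and
`phi -> 0` reduces the test to the exact binomial test on the pooled
total — an identity the test suite checks.

Dispersion is method-of-moments, `phi = max(0, (s^2 - m) / m^2)` on
normalized counts, in two modes: *pooled* (df-weighted pooled
within-condition variance around the grand mean) and *per-condition*
(per-group phi averaged). A gene is called differentially expressed only
when its BH-adjusted p-value is at or below `alpha = 0.01` under **both**
modes. Requiring two differently specified tests to agree mirrors the
practice of accepting only calls confirmed by two independent NB tools,
and is deliberately conservative.

With three replicates the raw moment estimate of phi is extremely noisy
and piles up at zero, which makes the exact test anti-conservative (a
gene whose replicates happen to agree gets tested as Poisson). Every phi
is therefore floored at the across-gene median of the raw estimates —
the conservative information-sharing rule of early NB testing tools, not
a trend or tagwise shrinkage. Under a 2,000-gene null simulation
(mu = 500, phi = 0.05, 3 vs 3) the fraction of genes with p <= 0.01 is
~0.012 with the floor (0.06 without), and the consensus calls none.

Percentages of down-regulated genes in summary tables are reported both
exactly and truncated to one decimal place, the convention such tables
are usually printed with.

## Monotony, reversals, and the negative-correlation test

A gene's monotony score is the mean, over B = 100 random
one-replicate-per-age draws (or all 54 combinations), of the Spearman
correlation between the drawn profile and an increasing ramp. Scores
above +0.75 classify the gene as monotonically up-regulated with age,
below -0.75 as down-regulated, otherwise non-uniform; the generous
threshold reflects the small number of replicates. Because the score
uses ranks only, warping the age axis changes nothing. Reversal sets are
the genes monotone in opposite directions in the two conditions.

The negative-correlation test asks whether a gene's control and treated
trajectories oppose each other. The observed statistic is the Pearson
correlation of the per-age mean profiles. The null distribution is built
from 1,000 iterations that permute the chronological order of the
treated profile (which member of the pair is permuted is a convention;
the null statistic is exchange-symmetric on null data) and pick one
random replicate per age on both sides. The one-sided p-value uses the
`(count + 1) / (n_iter + 1)` correction so p = 0 is impossible, and a
gene is significant when the observed correlation is negative and
p <= 0.05. For noise-free opposed ramps the exhaustive 4! = 24
permutation tail gives p = 1/24, which the Monte-Carlo p reproduces
within sampling error; on independent null pairs the rejection rate sits
slightly above the nominal 5% (<= 7%), the expected behaviour of the
discrete permutation p at 4 time points.

Significant genes are clustered with fuzzy c-means (fuzzifier m = 2,
tolerance 1e-6, at most 300 iterations, Bezdek update equations
implemented in-repo) on per-gene z-scored concatenations of the two
conditions' mean profiles. For each candidate cluster count (2..12) the
best of 30 random restarts by objective is kept; the count is chosen by
best average rank over the partition coefficient, the Xie-Beni index and
the mean silhouette of the hard assignment, with ties to the smaller
count. The objective is non-increasing within a restart (tested).

## Correlation networks and the difference network

Pairwise co-expression within a condition is the Pearson correlation of
temporal profiles, with replicates incorporated by resampling: each of
100 draws picks one replicate per age per gene independently (54
distinct profiles per gene under the 3/3/3/2 design; 2,916 joint choices
per pair), computes r and its two-sided t-test p-value (df = 2), and
both are averaged. An edge is kept when the mean p-value is <= 0.05;
with four ages that requires |r| near 1, so the per-condition networks
are sparse and "node count" means connected genes. Degree-frequency
distributions are summarized by an OLS fit of log10 f(k) on log10 k
(exponent gamma and R^2 reported; the fit recovers a planted exponent of
-0.8 to within 0.02 on exact synthetic frequencies).

The difference network compares co-expression *strength*:
`w_ij = |r_treated| - |r_control|`, sign-blind in the underlying
correlations, positive when the pair tightens under treatment. Edges
with |w| >= tau are retained. The default tau = 0.8 is calibrated on the
null: with four ages the mean correlation of two unrelated profiles is
|r| ~ 0.45 +- 0.25, chance |w| reaches 0.5 frequently, and only ~0.1% of
null pairs pass 0.8. Keeping the chance retention this low matters
because the enrichment statistic below needs the global pruned network
to be sparse *per gene*.

Gene-set enrichment follows the connected-fraction construction: a set
member is "connected" when it has a retained edge inside the set-induced
subgraph; the background is the fraction of genes outside the set with
any retained edge in the global pruned network; a one-sided Fisher exact
test (BH-adjusted across sets) flags sets with disproportionately many
connected genes. Sets with fewer than 4 genes in the universe are
skipped. Note the statistic's scale sensitivity: the background
saturates once the expected number of chance edges per gene approaches
one, so the pruning threshold and the size of the analysed universe must
be chosen together; the defaults are matched to desk-scale runs of a few
thousand genes (the pipeline caps the all-pairs stages at the 3,000 most
variable genes by default).

## Mutual-information networks and topology

MI between two mean temporal profiles uses the Gaussian-copula closed
form on the Spearman correlation, `MI = -1/2 ln(1 - rho_s^2)` nats. It
is nonnegative, invariant under strictly monotone transforms of either
profile, and exactly testable (rho = 0.6 gives 0.2231). Perfect rank
agreement maps to a cap of 5 nats. With four ages rho_s is very coarse
(11 possible values; |rho_s| = 1 occurs with probability 1/12 for
independent profiles), which limits what MI contrasts can resolve — see
limitations.

Dense MI matrices are pruned by the data-processing inequality: in every
triangle, edge (i,k) is removed when `MI_ik < min(MI_ij, MI_jk) - eps`
with eps = 0 (exact ties survive; decisions are taken against the
original matrix and applied at once, making the operation idempotent).

Nine topology parameters are computed per network: edge count, mean
degree, transitivity (3 triangles / connected triples), mean coreness,
mean nearest-neighbor degree, mean graph strength (weighted degree),
mean second-order neighborhood size, vertex connectivity, and "diameter"
defined as the *mean* shortest-path length over connected pairs (the
conventional max-eccentricity diameter is reported alongside). Shortest
paths use distance = 1/weight so strong dependencies are short; whether
a weight is a length or a proximity is a genuine convention choice, and
proximity is adopted because high MI means tight coupling. Percentage
changes between conditions are `100 (x_T - x_C) / x_C` for all
parameters except the diameter, which enters through its reciprocal so
that positive changes always mean a tighter network. Hubs are nodes with
strength above mean + 1 sd (sample sd; a regular network has no hubs);
hub turnover is the pair of set differences between conditions.

## The synthetic-data generator

`simdata` emulates the study conditions: 2,000 genes by default, two
conditions x four ages with 3/3/3/2 replicates, negative-binomial counts
via the Gamma-Poisson mixture (variance mu + phi mu^2; phi = 0 is the
documented Poisson special case) with phi = 0.05, log-normal baselines,
library size 2e6 jittered +-20% to exercise normalization, log-normal
gene lengths (ln-mean 7.3, ln-sd 0.6) clamped to >= 150 bp so RPKM is
well defined. Planted structure, 10%/5%/5%/5% of genes by default:

* per-age DE genes — the treated mean at one age is shifted by
  |log2FC| = 2, matching the effect size used in the recovery analyses;
* monotone genes — expected log2 expression moves 0.8 per age step in
  both conditions (about 1.7-fold per step, comfortably above the ~0.33
  log2 replicate noise, which is what "low noise" means here);
* anti-correlated genes — monotone up in one condition, down in the
  other, the planted analog of trend reversal;
* two 20-gene co-expression modules sharing a latent per-(condition,
  age) trajectory (sd 2.0 log2 units) with couplings 0.0/0.9 and
  0.9/0.0 — co-expressed only under treatment, respectively only in
  controls.

Two generator design points matter for what the recovery tests mean.
First, the module factor is drawn per (condition, age), not per sample:
replicate-resampled correlation only detects co-variation along the age
axis, so a per-sample factor would be planted "co-expression" that the
method is right to miss. Second, the coupled side is strong and the
decoupled side is exactly zero: a weak coupling of 0.1 times the factor
scale already rivals the measurement noise and produces substantial
correlation, because correlation measures signal-to-noise, not
amplitude.

What the generator does not emulate: batch effects, length/GC bias
within a sample, outlier libraries, dropout, isoform structure, and
realistic gene-gene correlation beyond the planted modules. Passing
recovery tests therefore demonstrate that the estimators detect the
structures they target at realistic noise levels — not that real data
meet these assumptions.

## Determinism and problem sizes

One global seed feeds a `SeedSequence` that derives independent stage
seeds; two runs with the same configuration write byte-identical
artifact directories (the manifest records configuration and versions,
not wall-clock time). All artifacts are TSV/JSON/GMT/edge-list text;
plots are opt-in.

Analyses in the test suite and the acceptance script run at desk scale,
chosen so each check finishes in seconds to a few minutes on one CPU:
2,000 genes for the end-to-end study and the DE calibration, 1,000 for
the enrichment demonstration (large enough that a 20-gene module is a
small library fraction — at a few hundred genes depth normalization
leaks the module trajectory into all genes of that condition), 500 for
monotony recovery, 1,000 pairs for permutation calibration.

## Known limitations

* Four time points bound everything rank-based: Spearman rho takes ~11
  values, chance perfect agreement has probability 1/12, and the
  Gaussian-copula MI inherits that coarseness. Single-gene hub-turnover
  detection is consequently noisy (majority detection, not certainty),
  and correlation p-values at df = 2 admit only near-perfect |r| as
  significant.
* The connected-fraction enrichment statistic saturates when the global
  difference network stops being gene-sparse; tau and the universe size
  must move together.
* The conditional exact test conditions on raw group totals, so its
  p-values are only approximately invariant to rescaling a single
  sample (decisions away from the threshold are stable; borderline
  p-values can move).
* The dispersion floor trades a little power for calibration; genes with
  genuinely below-median dispersion are tested conservatively.
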