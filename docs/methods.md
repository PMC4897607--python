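# Methods

`commphylo` implements the community-phylogenetics workflow used to ask how
assembly processes change along a successional chronosequence: are the
species that co-occur in a plot more closely related than chance
(environmental filtering leaves phylogenetic clustering) or less
(limiting similarity leaves overdispersion), and does the answer shift as
succession proceeds?  This note records the models, conventions and
numerical choices, and what the synthetic benchmarks do and do not show.

## Phylogeny and distances

The regional phylogeny is a rooted tree with branch lengths in Myr; all
phylogenetic quantities reduce to patristic (cophenetic) distances, the sum
of branch lengths on the tip-to-tip path.  Megatree-derived trees usually
need dating, which `bladj_calibrate` provides: given a table of fixed node
ages (plus a root age) and tips pinned at 0, every undated node receives an
age by even interpolation.  Nodes are processed from the root toward the
tips; an undated node interpolates between its parent's (already fixed) age
and its *nearest* dated descendant, nearest by count of intervening nodes,
ties resolved toward the older candidate.  On an unbranched chain this is
exactly the classic even division of the dated-to-dated interval; at
branchings the nearest-anchor rule makes the result deterministic.  Branch
lengths are then recomputed as age differences, so the calibrated tree is
ultrametric (checked at 1e-6 relative tolerance) and calibration is
idempotent.  A constraint dating a descendant older than its ancestor is an
error naming both nodes.

Faith's PD sums the branch lengths of the subtree spanning a species set.
By default the subtree is rooted at the set's MRCA, so single-species PD is
0 and small sets are not inflated by the path to a distant global root;
`rooted="root"` includes that path instead, since both conventions are
common.

## Diversity metrics

Per plot (alpha): richness; Gini–Simpson diversity 1 − Σp², the most common
reading of "Simpson diversity" (the inverse form 1/Σp² is also provided);
Faith's PD; MPD, the mean patristic distance over distinct pairs of
co-occurring species; and MNTD, the mean distance from each species to its
nearest co-occurring relative.  Abundance weighting uses relative coverage
p: weighted MPD is Σᵢ≠ⱼ pᵢpⱼ d(i,j) / Σᵢ≠ⱼ pᵢpⱼ — conspecific self-pairs
are excluded from the weight total so the statistic stays a mean of
between-species distances (some implementations keep them; the difference
is the factor 1 − Σp²) — and weighted MNTD weights each species' nearest-
neighbour distance by its coverage.  Plots with one species have no
pairwise structure; MPD/MNTD are missing there and drop out of stage
summaries with a logged count.

Between plots (beta), enumerated only within a succession stage: 1 −
Jaccard on species sets; COMDIST, the mean patristic distance over all
cross-community species pairs (shared species contribute distance 0, the
classic convention; a flag excludes conspecific pairs instead); and
COMDISTNT, the mean distance from each species to its nearest relative in
the other community.  Unweighted COMDISTNT averages the pooled per-species
minima of both directions; the weighted form averages the two directions'
coverage-weighted means (each direction's weights sum to 1), which keeps
the metric symmetric under unequal richness.  With occurrence weights
COMDISTNT ≤ COMDIST always (minima vs means).

## Null model and standardized indices

The null model randomizes the plot × species occurrence matrix while
preserving each plot's richness and each species' occurrence frequency —
the independent/trial-swap family.  A trial picks two plots and two species
at random and flips the 2×2 submatrix when it is a checkerboard.  One chain
serves each analysis: burn-in of 10 × fill trials (fill = number of
occupied cells), then one null sample every 1 × fill trials; both factors
are configurable.  On the 2×2 checkerboard, whose margin class has exactly
two members, chains of 20 trials sample both states 50:50 (tested at 3σ
over 10,000 chains).

Abundances ride along: when a flip vacates a cell, the plot's coverage
value reattaches to the species that moved in.  Row sums (and hence the
relative-coverage normalization), per-plot richness, per-plot multisets of
coverage values, and occurrence frequencies are all invariant, so the same
ensemble serves occurrence- and abundance-weighted metrics and no separate
abundance null is needed.

Indices follow the standard sign convention: NRI = −(MPD_obs − mean
MPD_null)/sd MPD_null, NTI likewise for MNTD, betaNRI/betaNTI likewise for
COMDIST/COMDISTNT; positive values mean closer relatedness (or lower
turnover) than expected.  Defaults: 999 randomizations, null sd with n−1
degrees of freedom.  A degenerate null (sd = 0, e.g. tiny pools whose
margins admit a single matrix) yields index 0 with a warning and is
excluded from t-tests, avoiding infinities.  The batch functions
(`ses_alpha`, `ses_beta`) score every plot/pair against one shared chain —
the classic batch design, and the only tractable one for the ~939
within-stage pairs of the full layout; the single-target wrappers
(`nri_nti`, `beta_nri_nti`) instead derive a per-target RNG substream from
the master seed so evaluation order and parallelism cannot change any
number.  Everything is bit-for-bit reproducible under a fixed seed.

The randomized pool is the supplied matrix itself — all plots, all species
of the regional pool, matching the convention of randomizing within the
full regional survey.  A consequence worth knowing: if every plot in the
matrix was shaped by the same process, the margins already encode that
process and the indices are pulled toward 0.  The mechanism-recovery
benchmarks therefore embed mechanism plots alongside neutral context plots,
and life-form subset analyses randomize within the subset matrix.

## Stage-level inference

Diversity metrics are compared across the six stages with one-way ANOVA
followed by the Student–Newman–Keuls stepwise range procedure: group means
are rank-ordered and the range of each subset of r adjacent means is tested
against the studentized-range quantile q(α, r, df_error); a non-significant
range closes its sub-ranges.  Unbalanced stages (9 vs 37 plots) use the
harmonic mean of all group sizes, the usual convention for range tests on
unequal n.  Homogeneous ranges become a compact letter display with 'a' at
the largest mean.  If the pooled error variance is zero the ANOVA is
flagged degenerate (F undefined, all letters 'a').  Standardized indices
are tested against zero per stage with two-tailed one-sample t-tests; the
test unit for beta indices is the plot pair (a per-plot averaging variant
would be easy to add, but pair values are what the pipeline tabulates).
Constant vectors are flagged untestable rather than producing t = ∞.

## Synthetic data: what it emulates

The generator exists so every stage of the pipeline can be validated with
known truth.  A pure-birth (Yule) tree provides the regional pool
(exponential waiting times with rate λk, uniform lineage choice, an extra
exponential interval after the last split, rescaled to a 100-Myr root); a
Brownian trait (σ² = 1, so tip sd ≈ 10) carries the niche signal.  Three
assembly modes: neutral (uniform sampling without replacement), filtering
(sampling weight ∝ exp(−(trait−optimum)²/2σ²)), and limiting similarity
(shuffled candidates accepted iff ≥ δ Myr from all accepted species, δ
relaxing ×0.9 whenever the pool is exhausted).  Abundances are lognormal
(meanlog 0, sdlog 1) renormalized to coverages.

The default six-stage design mirrors the dimensions of a semi-arid
temperate old-field-to-forest survey: plot counts (9, 9, 9, 37, 16, 10), pool 356 with 129 woody species,
per-plot richness rising (8, 10, 12, 16, 18, 20).  Succession is emulated
space-for-time by varying the mechanism per stage: limiting similarity of
weakening strength (δ = 150, 110, 75 Myr) for stages 1–3, neutral at the
transitional stage 4, filtering of increasing strength (σ = 2.0, 1.0) for
stages 5–6.  The strengths were set against the measured pool geometry —
pairwise distances concentrate near 150 Myr, so δ below ~100 barely binds,
and a σ of 1–2 trait units gives an effective filtered pool of ~40–90 of
356 species; weaker settings leave the designed overdispersed→clustered
gradient inside sampling noise.  Woody species are the 129 highest-trait
tips (clade-biased because the trait is Brownian) and the late-stage filter
optimum is the woody trait mean, so the woody fraction rises along
succession.  For mechanism recovery, `focal_clade` picks the 15–40-tip
clade with the highest trait discriminability (offset of the clade mean in
units of the clade's own sd) and the filter centres there; quantile-based
optima occasionally land in trait regions shared by several clades, where
a trait filter genuinely does not produce phylogenetic clustering.

What the generator does *not* emulate: dispersal limitation and spatial
autocorrelation, temporal dynamics within a plot, abundance–occupancy
correlations, observation error, and polytomy-rich megatree topologies
(the pool tree is binary; all metrics nevertheless accept polytomies).
Passing benchmarks therefore show the estimator chain is correct and
calibrated under the stated generative processes, not that real field data
meet those assumptions.

One empirical note from the benchmarks: between-plot turnover of
limiting-similarity plots is *not* overdispersed relative to the swap null.
Deterministic min-distance assembly reuses the most isolated taxa in every
plot, so plot pairs share them and observed COMDIST falls as much as
within-plot overdispersion raises it; across δ = 60–120 the mean betaNRI of
such pairs stays near 0.  The beta-index recovery surface is therefore the
filtering direction (betaNRI > 0 for pairs of filtered plots) plus
calibration (betaNRI ≈ 0 for neutral pairs).

## Problem sizes and tolerances

Bundled benchmarks use: 200 random trees of ≤ 8 tips for brute-force oracle
equality (relative tolerance 1e-10); 10 neutral pools × 100 plots
(richness 5–15 from 64 species, 399 randomizations) for SES calibration —
measured mean ≈ 0, sd ≈ 1.06, two-tailed rejection ≈ 5% at |SES| > 1.96;
50 mechanism plots + 50 context plots from a 128-tip pool (199
randomizations) for recovery; the full 90-plot design at 199 randomizations
for the end-to-end pattern.  Floating-point equality in metric tests is
exact-arithmetic-derived where possible (hand-computable trees) and 1e-9
relative elsewhere; ultrametricity and age checks use 1e-6 relative.
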