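# Methods notes

This note records the statistical model behind `songdiv`, the defaults
and why they were chosen, the numerical conventions, and what the
synthetic-data generator does and does not emulate.

## Data model

A feature table holds one row per recorded individual and one column per
acoustic measurement, keyed by a short code: a quantity digit 1–9
(duration s, peak/min/max frequency Hz, repeat count, note count,
syllable count, slur U/D, proportion %), an optional syllable letter a–h,
and an optional note digit — `1` is whole-song duration, `1b` the
duration of syllable b, `1b1` the duration of note 1 of syllable b. Slur
(quantity 8) is the single categorical quantity. Missing cells are always
explicit (empty or `NA` in CSV, NaN in memory), never zero: a bird that
does not sing syllable d simply has no measurements for it.

## Gower dissimilarity

Numeric features are compared as range-normalised absolute differences,
categorical features as 0/1 mismatches, averaged over the features
observed in *both* individuals. Conventions:

- Ranges are max − min over exactly the table the matrix is built from.
  A within-taxon analysis therefore scales by that taxon's own spread,
  a pooled between-taxa analysis by the pooled spread. This matters: the
  same two individuals can be more dissimilar relative to one taxon than
  relative to a pooled pair.
- Constant (zero-range) numeric features carry weight 0 — they are
  excluded from numerator and denominator rather than contributing 0/0.
- Count variables (repeats, notes, syllables) and the proportion are
  treated as interval-scaled numerics, not ordinal categories; they are
  quantities on a meaningful scale.
- A pair with no co-observed informative feature has an *undefined*
  dissimilarity, reported as an explicit marker. Clustering refuses
  undefined matrices; the pipeline drops such individuals first and logs
  them.

## PAM and the choice of k

k-medoids minimises the summed dissimilarity of individuals to their
cluster exemplars. When the number of candidate medoid sets C(n, k) is
at most 10 000 the optimum is found exactly by enumeration (with a
lexicographic tie-break), because at the scale of these analyses
(tens to low hundreds of individuals, k ≤ 8) exact search is affordable
for small k and removes the local-optimum failures a pure local search
exhibits on weakly structured matrices (on random matrices the classic
heuristic lands in a single-swap local optimum a few percent of the
time). Larger search spaces fall back to the classic BUILD+SWAP local
search, accepting the single best cost-reducing exchange per iteration;
all ties break toward the lowest individual index so results are exactly
reproducible and order-stable.

k is chosen by scanning k = 2–8 and keeping the highest average
silhouette width (ASW). Silhouette conventions: singletons score 0, as
does the degenerate a = b = 0 tie. When even the best ASW falls below
`weak_asw_threshold` (default 0.25, configurable) the profile reports
k = 1 with a weak-structure flag: an ASW that low means the "clusters"
are not meaningfully more cohesive than their surroundings. The 0.25
default follows the common reading of silhouette values below ~0.25 as
no substantial structure; it is deliberately exposed because the
boundary is a judgment call, and the full ASW-by-k profile is always
reported alongside.

Cluster/geography concordance is the fraction of individuals correctly
co-labeled under the best one-to-one matching of clusters to regions
(rectangular Hungarian assignment; clusters left unmatched count as
disagreement). One-to-one is the stricter convention: with two regions,
an assignment independent of geography scores ≈ 0.5, and a many-to-one
mapping cannot inflate agreement by funnelling every cluster into the
majority region.

## Mixed-data PCA

The FAMD/PCAmix construction: numeric columns are standardised with the
population (1/n) variance; categorical levels are one-hot encoded,
centred, and each level column scaled by 1/√(level proportion); the
combined matrix is decomposed with row weight 1/n. Consequences used as
test identities: with only numeric columns the eigenvalues equal those
of correlation-matrix PCA; a single m-level categorical variable yields
total inertia m − 1; in general the eigenvalue sum equals
(#numeric) + Σ(levels − 1) for complete data.

Missing data follow the mean/zero rule: numeric cells take the column
mean of observed values, categorical cells contribute an all-zero
indicator row. Zero-imputed categoricals deflate level proportions, so
a categorical variable with missing cells contributes slightly *more*
than levels − 1 to the inertia; `total_inertia` is therefore always
reported as the realized trace, and the percentage-of-variance figures
sum to 100 by construction.

Component signs are fixed by flipping each component so its
largest-magnitude column loading is positive; eigenvector sign is
otherwise arbitrary and would make downstream comparisons
nondeterministic. Numeric loadings are variable–component correlations;
categorical variables report summed squared level loadings. The
top-loading feature of a component is the variable with the largest
squared loading, ties resolved by column order. No variable
transformation is applied by default; a user who wants log-scaled
durations or frequencies transforms the table before fitting (Δp is
invariant to this, PCA and Gower are not).

Degenerate columns (all-missing, constant numeric, complete single-level
categorical) abort `famd` with a named error; the pipeline drops them
with a log entry before fitting, since a screen over many simulated
tables must not die on a boundary draw.

## Permutation test

All n(n−1)/2 pairwise dissimilarities are partitioned into within-east,
within-west and between categories. The statistic for a comparison is
the difference of category means. The null distribution permutes taxon
labels at the individual level, preserving group sizes, and re-derives
the categories from the fixed matrix — resampling dissimilarity entries
independently would ignore that each individual appears in n − 1 pairs.
p = (1 + #{null ≥ observed}) / (B + 1), so p ≥ 1/(B+1) and the test is
exact under exchangeability. Between-vs-within comparisons are one-sided
("greater": is between-taxa dissimilarity larger?); the within-vs-within
comparison is two-sided. B defaults to 10 000. The implementation
evaluates category sums through the indicator quadratic form
eᵀDe/2, which makes thousands of replicates effectively free and lets
calibration studies run at full size.

Both Benjamini–Hochberg FDR and Bonferroni adjustments are computed and
reported side by side; a batch of m pair analyses corrects over the full
3m-test family (27 tests for a nine-pair study, per-test criterion
0.05/27 ≈ 0.00185).

## Δp and effect sizes

For each feature the two populations' observed values are pooled into a
joint empirical CDF (right-continuous, percentile scale 0–100); each
population's coordinate is the percentile of its median (midpoint
convention for even n — the ECDF is defined at unobserved values). Δp is
the Euclidean distance between the two coordinate vectors, hence bounded
by 100·√K for K features; working in percent units rather than [0, 1]
keeps multi-feature scores in the readable 10²-range. Δp is invariant
under any strictly increasing per-feature transform, symmetric in the
populations, and tolerant of missing cells (each feature uses whatever
is observed). Categorical slur features are excluded by default — a CDF
presumes orderable values — with an opt-in 0/1 encoding flag. No
normalisation by feature count is applied; reports carry
`features_used` so the reader can judge comparability across pairs with
different measurement sets.

Hedge's g uses the (n−1)-weighted pooled SD and the small-sample
correction J = 1 − 3/(4N − 9). The two-sample t-test offers pooled
(df = n_A + n_B − 2) and Welch–Satterthwaite variants. Spearman's ρ uses
average ranks; its two-sided p-value is exact (full rank-permutation
enumeration) for n ≤ 9 without ties, and the t approximation otherwise
— divergence-time studies at this scale involve ~9 pairs, where the
exact null matters.

## Synthetic-data generator

`generate_pair` emulates the structure of real song-measurement tables:
default n = 50 individuals per taxon and K = 20 features (whole-song
duration, syllable count, one slur, a repeat count, and duration/peak/
min/max frequency for four syllables) — mid-range of typical designs
(25–75 individuals, 16–42 measurements per pair). Base distributions:
durations log-normal (median 0.1–2 s, log-sd 0.3), frequencies normal
(centres 2–9 kHz, sd 200–800 Hz), counts Poisson (λ 1–10), slur
Bernoulli. Divergence is injected as per-feature location shifts in
within-population SD units (log-scale for durations, λ + shift·√λ for
counts), on five frequency features by default.

Missingness is structural, not cell-wise: each syllable is present with
a configurable probability (defaults a:1.0, b:1.0, c:0.9, d:0.75), and
an absent syllable blanks all its codes at once; the syllable-count
feature tracks realised presence, so counts and missingness are
consistent the way variable song structure makes real tables uneven. A
cell-wise MCAR rate is available separately for stress tests. The slur
probability defaults to 0.9 in both taxa: slur direction is
taxon-typical in oscine song, and a per-individual coin flip would be a
full-weight binary noise feature that no real dataset exhibits —
with it, clustering legitimately locks onto slur rather than frequency
shifts. Localities are two 2-D Gaussian clouds (east/west centroids,
sd 3°).

One global seed fans out to substreams keyed by (role, side, feature
code), so adding or removing features never shifts the draws of the
others, and every table is bit-reproducible.

`inject_local_variant` emulates a localized within-taxon variant: a
geographically contiguous subset (inside a given box, or the requested
fraction with the lowest longitude) gets a location shift on a numeric
feature; injected rows are flagged in metadata for test oracles, and the
realized bounding box is stored so the within-taxon screen can receive
the candidate region without seeing the flags. The reference variant
scenario shifts the *whole four-feature block of one syllable* by 4 sd
on a 16-feature table: a real song variant differs in a syllable's worth
of correlated measurements, and — mechanically — a single standardized
column has unit variance like every other column, so one isolated
feature can never dominate PC1 no matter how large the shift; the
correlated block can, and the screen then reliably reports one of the
altered codes as the top loader.

What the generator does not emulate: acoustic waveforms, temporal or
spatial autocorrelation of song culture (dialect geography beyond two
Gaussian clouds), inter-feature correlation within an individual beyond
the variant block, observer/measurement error structure, and
hybrid-zone intergradation. Passing tests therefore show the pipeline
recovers known structure under idealised independence — they do not
certify behaviour on field data with correlated features or clinal
variation.

## The two-criteria variant call

`run_within_taxon_analysis` calls a variant only when (1) the silhouette
scan finds real structure (k ≥ 2 and not weak) *and* (2) the clusters
track the candidate geographic region with agreement at or above
`concordance_threshold` (default 0.8). This operationalises the
screening logic of within-taxon regiolect detection: taxa commonly show
statistical clusters (song types) with no geographic basis, and those
must not be called variants. The 0.8 default sits well above the ≈0.5–
0.65 agreement that geography-independent clustering produces and below
the ≈0.95+ agreement of genuinely localized variants in simulation.

## Problem sizes and reproducibility

Simulation studies in the test suite and acceptance script use the
generator's default conditions: 500 null replicates at B = 199 for
type-I-error calibration, 100 replicates for power and for the variant
screen's recovery/specificity, and B = 9 999–10 000 for single-analysis
p-values. These sizes give Monte-Carlo standard errors comfortably
below the margins being tested. Every stochastic operation takes an
explicit seed; pipeline reports embed the seed, package version, and a
hash chain over stage outputs, and re-running with identical inputs
reproduces every numeric field exactly.

## Known limitations

- Gower weights all features equally; a measurement set dominated by one
  syllable weights that syllable's evidence accordingly. Reports carry
  the feature list rather than attempting reweighting.
- Δp values are relative to the pooled dataset of a pair; comparing Δp
  across pairs with very different measurement sets is informative but
  not strictly scale-equivalent (the √K bound differs). `features_used`
  is always reported.
- The weak-structure threshold and concordance threshold are judgment
  boundaries, exposed as configuration rather than hidden constants.
- The permutation test assumes exchangeability of individuals under the
  null; spatially autocorrelated sampling would violate this and is not
  modelled.
- With categorical missingness, mixed-PCA inertia slightly exceeds the
  complete-data identity (see above); variance percentages remain exact.
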