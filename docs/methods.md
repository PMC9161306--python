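# Methods

## Data model and preprocessing

The unit of analysis is one molecule (metabolite or phosphopeptide) in
one genotype, measured on the log2 scale in four conditions — end of
day/root (DR), end of day/shoot (DS), end of night/root (NR), end of
night/shoot (NS) — with 4–6 biological replicates per condition. The
package consumes post-imputation, post-normalization tables; raw mass
spectrometry processing is out of scope.

Outliers are flagged per molecule per condition group with the
Iglewicz–Hoaglin modified z-score: a value is removed when
|0.6745 (x − median) / MAD| exceeds 5. Grouping by condition is a
deliberate choice — flagging across conditions would let genuine
condition effects masquerade as outliers. When the MAD is zero the mean
absolute deviation from the mean scaled by 1.2533 substitutes; when that
is also zero nothing is flagged. Groups of fewer than three values are
never flagged, and a condition reduced below two replicates is treated
as absent rather than imputed. Outlier classification operates on the
log2 values; `flag_outliers` is scale-invariant under positive affine
transforms, so the choice is immaterial for multiplicative rescalings
but is exposed to the caller regardless.

Per-condition summaries use the sample (n−1) standard deviation
throughout, matching the descriptive routines' defaults, since this sd
is the denominator of the condition deviations below. The
between/within variance ratio is the sample variance of the condition
means over the pooled within-condition variance. A molecule is *flat*
when the Kruskal–Wallis rank test over its replicate groups has
p > α_flat (default 0.05); flat molecules are excluded from connections
and clustered separately. Pattern z-scores standardize the four
condition means with population (n) normalization — they serve
clustering geometry only, so the choice of denominator is cosmetic; the
degenerate all-equal case yields NaN z-scores and is treated as flat.

## Concordance index

Deviations d_k = (x̄_j − x̄_i)/sd(x)_i are computed for the 12 ordered
condition pairs in the fixed order (DS|DR, NR|DR, NS|DR, DR|DS, NR|DS,
NS|DS, DR|NR, DS|NR, NS|NR, DR|NS, DS|NS, NR|NS); a fixed enumeration
makes serialized outputs bit-stable. Two edge cases are defined rather
than left to crash:

* **sd = 0 with a genuine mean gap** maps to a signed infinity sentinel
  and therefore lands in the outermost deviation class (component ±2) —
  a real difference with zero spread is maximal evidence, not an error;
* **absent conditions** invalidate the touching pairs, which contribute
  0 (neutral) to the index; the count of valid components is carried in
  the output so users can filter pairs supported by few conditions.

Combined deviations z_k = sign·sign·min(|·|,|·|) are discretized by the
class table ([1,2)→0.25, [2,3)→1, [3,5)→1.5, [5,10)→1.75, [10,∞)→2,
odd in the sign), and the components sum to I_C(−), I_C(+), and
I_C ∈ [−24, 24]. All components are exact multiples of 0.25 in binary
floating point, so threshold comparisons at 6, 7 or 10 are exact and no
tolerance is needed anywhere in the index arithmetic.

The Spearman co-filter pairs observations by (condition, replicate
index), truncating each condition to the smaller replicate count; this
preserves n ≈ 16–24 paired points per pair. Midranks handle ties; the
two-sided p-value uses the t-approximation, which is adequate from
n ≈ 10 upward. Fewer than 4 paired points force p = 1 so the α = 0.05
filter always removes such pairs. The pair table computes the identical
quantities through a vectorized route (rank transform along rows of a
NaN-masked pairing matrix); unit tests pin the vectorized route to the
scalar one and to `scipy.stats.spearmanr`.

## Null model

To calibrate false-positive rates, molecules are replaced by surrogates
in three modes: randomize the metabolite block, the phosphopeptide
block, or both. Each surrogate draws one condition mean per condition
from a three-parameter Gamma distribution fitted to the molecule's own
condition means, then draws the experimental number of replicates from
a normal centered on the *drawn* mean with the *experimental*
per-condition sd. Centering on the drawn mean is the only reading under
which the Gamma draw has any consequence; using the experimental sd
preserves the within-condition noise level, which is what makes the
surrogate's deviations comparable in magnitude to the real ones.

The Gamma fit uses the method of moments on the (≥ 3) condition means:
shape = 4/g₁², scale = sd·g₁/2, location = mean − shape·scale, which
reproduces the sample mean and variance exactly. Maximum likelihood is
ill-posed with four points and a free location. Samples with skewness
g₁ ≤ 0.05 are fitted on their reflection and drawn mirrored; a
zero-variance sample yields a degenerate constant fit. Near-symmetric
samples cap g₁ at 0.05, which makes the fit effectively normal while
keeping the first two moments exact.

FPR curves report, per threshold t, the share of pairs with the measure
at or beyond t — values ≥ t on the non-negative branch, ≤ t on the
negative branch — for the experimental and the simulated table. The
default grids are quarter-integers spanning [−24, 24] for I_C and 100
equal classes on [−1, 1] for ρ.

A structural property of this null is worth stating: it preserves each
molecule's pattern *strength* (the spread of its condition means) while
destroying pattern *agreement* between molecules. Consequently the
simulated share of |I_C| ≥ 6 pairs is small only when the data's
between-condition spread is modest relative to replicate noise, or when
concordance in the experimental data is genuine and widespread; a
dataset consisting mostly of strong random-polarity patterns retains a
sizeable chance share on both signs. The test suite exercises both
regimes.

## Clustering and between-genotype distance

Standardized patterns are clustered per genotype, or pooled across
genotypes, with k-means (k-means++ seeding, 100 restarts, at most 300
iterations, Euclidean) or agglomerative clustering with Ward linkage on
Euclidean distance — Ward is chosen to match the k-means variance
geometry and is exposed as an option. Flat molecules always receive the
reserved label "Z" and never enter the partition. The default k = 13
for metabolite patterns; a silhouette scan over a configurable k-range
supports choosing k elsewhere.

The between-genotype distance of a molecule is

    d_GT = w_c · change + w_e · euclid,   w_c = w_e = 0.5,

where *change* is the fraction, over an ensemble of clustering
configurations ({hierarchical, k-means} × {k−2, k, k+2}) and genotype
pairs, of differing cluster labels, and *euclid* is the molecule's
summed pairwise Euclidean distance between its z-patterns across
genotypes, divided by the dataset maximum so the component tops out at
1. Both components lie in [0, 1]; the equal weighting and the
max-normalization are package choices (no canonical weighting exists),
so printed d_GT values are comparable within a dataset but not across
datasets. Molecules flat in all genotypes, or present in fewer than
two, carry NaN.

## Over-representation profiles

For an entity occurring K times in a ranked list of length N, position
n of its profile is the one-sided Fisher exact p — equivalently the
hypergeometric tail P[X ≥ k] — for the 2×2 table
[[n−k, k], [(N−K)−(n−k), K−k]]. One-sidedness is deliberate: the
procedure scans for over-representation only. n runs to the top 10%
(interaction tables) or top 25% (molecule tables); the Bonferroni
divisor is the number of positions in the entity's own profile (the
per-entity family), exposed as configuration. The profile condenses to
x_k = Σ (n_top − i + 1)(−log10 p_adj,i), so early-list enrichment
dominates. Per genotype, entities are ranked by x_k descending with
ties broken lexicographically, and scaled to ρ_SC = rank/(count+1),
which realizes the open interval (0, 1) — the alternative
(rank−1)/(count−1) hits the endpoints and is rejected. Lists are
deterministically sorted (ties by id) in both directions before
profiling. A phosphopeptide mapping to several functional bins counts
as an occurrence of each; dotted bin codes can be truncated to any
leading depth.

## Networks

Connections require I_C ≥ ic_min (inclusive, default 7 for network
building, 6 for screening), Spearman p ≤ 0.05, and non-flat partners.
Edges aggregate connections per (metabolite, truncated bin, genotype)
with the arithmetic mean of member I_C values and the member count;
multi-bin phosphopeptides contribute to each mapped bin, and
unannotated ones fall into bin "unknown" with a logged warning.
Discordant mirror edges (I_C ≤ −ic_min) are computed behind a flag but
excluded from the default network. The bipartite multigraph keeps one
parallel edge per genotype and is exported as GraphML/GML plus a flat
edge list; layout is left to external tools.

## Synthetic data generator

The generator emulates the study dimensions — 42 metabolites, 3,330
phosphopeptides, 3 genotypes, 4 conditions with 4–6 replicates — with
four planted archetypes on the log2 scale: tissue-dominant
(−1,+1,−1,+1), time-dominant (+1,+1,−1,−1), interaction (+1,−1,−1,+1),
flat (0,0,0,0), scaled by an effect size (default 2 log2 units) around
a molecule-specific baseline (normal, mean 10, sd 2 log2 units), with
additive Gaussian replicate noise (default sd 0.5 log2 units). The
default effect/noise ratio of 4 makes planted pairs recoverable but not
trivially so. Polarity signs are random, so same-archetype pairs split
into concordant and discordant ground truth; the default archetype
mixture is 30/30/20/20 (tissue/time/interaction/flat), a composition
with a clear non-flat majority and a realistic flat minority. Per-
genotype sign flips can be planted to create between-genotype pattern
changes.

The generator does **not** emulate mass-spectrometry missingness,
intensity-dependent noise, correlated replicate structure, or the
skewed abundance distribution of real LFQ data. Passing tests therefore
demonstrate the correctness and calibration of the machinery under
clean Gaussian conditions, not performance on real acquisitions;
quantitative claims about the deposited study tables require those
tables (see `tests/test_acceptance.py`).

## Problem sizes and numerical conventions

The pair-universe check runs at full study scale (42 × 3,330 = 139,860
pairs, a few seconds vectorized); other simulation-based tests use
reduced universes (tens of metabolites × tens-to-hundreds of
phosphopeptides, 1–3 simulated datasets per mode) chosen to keep the
suite quick while leaving Monte-Carlo margins wide. Invariant checks
compare I_C values exactly (quarter-integer arithmetic); floating
comparisons elsewhere use relative tolerances of 1e−9 (algebraic
identities) or the stated Monte-Carlo bands. TSV output prints doubles
with 17 significant digits and is read back with round-trip float
parsing, so write-then-read reproduces values bit-exactly; reruns of
the pipeline with identical configuration are byte-identical (the run
manifest records configuration, input hash and package version, and
contains no timestamps).

## Known limitations

* The index treats the 12 ordered pairs as exchangeable evidence; the
  six reversed duplicates are not independent, so I_C magnitudes should
  be compared against the simulated null rather than read as counts of
  independent agreements.
* Spearman pairing by replicate index assumes replicate order is
  meaningful across molecules (samples processed together); if
  replicate labels are arbitrary within conditions, the filter is
  conservative noise.
* d_GT depends on the configured clustering ensemble and the dataset's
  own maximum divergence; it is a within-dataset ranking device.
* The Gamma null preserves condition-mean spread; datasets dominated by
  strong patterns retain non-trivial chance concordance (see the null
  model section).
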