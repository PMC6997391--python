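# Methods

This package implements the pattern-plus-mechanism workflow used to analyse
site-by-taxon survey data collected along strong environmental gradients
(the motivating case is benthic macroinfauna along estuarine salinity
gradients): elements of metacommunity structure (EMS) with null models,
NODF nestedness, PCNM spatial eigenvectors, VIF-pruned environmental
predictors, and three-way variation partitioning by (partial) redundancy
analysis. A synthetic-data module generates incidence matrices realizing
each idealized metacommunity structure and Gaussian-niche gradient
communities, so every stage is testable without field data.

## Ordination

EMS metrics are computed on the incidence matrix reordered by the first
non-trivial axis of correspondence analysis (reciprocal averaging). The
axis comes from the SVD of the chi-square standardized correspondence
matrix `D_r^{-1/2} (P - r c') D_c^{-1/2}`; row and column principal scores
sort sites and taxa along the dominant latent gradient. Only the first axis
is used. Sign indeterminacy is resolved by orienting the axis so its
correlation with the input row order is non-negative — a pure reporting
convention; every downstream statistic is invariant to it (and to any
row/column shuffling of the input). Ties in scores are broken by original
index order, so output files are byte-reproducible. Matrices of rank < 2
(e.g. all rows identical) raise a degenerate-ordination error.

## Elements of metacommunity structure

**Coherence.** The number of embedded absences — zeros strictly inside a
species' range (column direction) and inside a site's composition (row
direction) — is compared with a fixed-row, proportional-column ("r1") null:
each simulated site keeps its observed richness, species are drawn without
replacement with probability proportional to their observed frequency
(implemented as a vectorized exponential-race weighted sample). Every
simulated matrix is independently re-ordinated before counting; simulated
empty species columns are dropped, and a draw whose ordination is
degenerate is retried once, then skipped with a log entry. Both directions
are counted by default; `axis="columns"` restricts to species ranges for
cross-checks against implementations that count one direction only.

**Turnover.** Following the range perspective, embedded absences inside
each species' range are imputed (`fill_ranges`) before counting
replacements: over all unordered species pairs and site pairs, the cases
where one species is present where the other is absent and vice versa
(for a pair this equals |sites with A only| x |sites with B only|). The
null shifts each species' contiguous range of length L uniformly among the
n − L + 1 feasible positions, independently across species, no wrap-around.
Species occupying every site contribute no randomness; if all do, the null
is degenerate and flagged.

**Null summaries.** Each test reports observed value, simulated mean and
sd, z = (observed − mean)/sd and a two-tailed normal-approximation p (an
empirical two-tailed p is available via `empirical_p=True`). Note that some
published tables print the z with the opposite sign (positive when the
observed value lies *below* the null mean); classification uses the sign of
the deviation directly, so the convention does not affect labels. Both
tests hold their nominal size: over 200 seeds of matrices drawn under the
respective null, rejection rates at alpha = 0.05 fall within [0.02, 0.10].

**Boundary clumping.** Each species' range contributes its start and end
position as boundaries, *censoring endpoints that lie on the first or last
ordinated site*: a range reaching the matrix edge may extend beyond the
sampled gradient, so no boundary is observable there. Censoring is what
makes the nested species-loss subtypes identifiable — in a nested
metacommunity every range is anchored at the richest end, and counting
anchored endpoints would mark every nested matrix as clumped regardless of
how species are actually lost. `include_edges=True` restores the uncensored
count for comparison with other software. Morisita's index
`I = n Σ f(f−1) / (F(F−1))` is computed over the interior positions, with a
chi-square goodness-of-fit test against uniformity (df = interior positions
− 1); the chi-square tail follows the direction of the index (upper tail
for I ≥ 1, lower tail for I < 1, i.e. significant *evenness* requires a
chi-square smaller than expected).

**Decision tree.** Significantly *negative* coherence (more embedded
absences than the null) → checkerboard; non-significant → random;
significantly positive → branch on turnover. Significant negative turnover
→ nested subsets, with species loss clumped (I > 1, chi-square
significant), hyperdispersed (I < 1, significant) or random (otherwise);
significant positive turnover → Clementsian / evenly spaced / Gleasonian by
the same three-way clumping branch. Non-significant turnover takes the same
branches by the *sign* of the deviation, flagged quasi-. An exactly zero
turnover deviation (possible only in degenerate all-full-range matrices) is
assigned to the positive branch. Alpha defaults to 0.05.

## NODF

For each ordered pair of rows (and columns) with strictly decreasing
marginal fill, the paired contribution is 100 x (shared presences) /
(fill of the poorer line); equal fills contribute zero. Components average
these contributions over row pairs and column pairs separately, the total
over all pairs. `order="by_fill"` sorts by decreasing fill first (ties by
original index); `order="as_given"` evaluates the matrix as passed. Values
agree with vegan's `nestednodf` to 1e-8 on frozen fixtures. Significance
uses either a fixed-row/fixed-column sequential-swap chain (burn-in 10x the
cell count, thinning 1x, achieved swaps logged) or the r1 null. The
fixed-fixed null is deliberately conservative: margins alone nearly
determine NODF for strongly nested matrices, and a perfect staircase is
*uniquely* determined by its margins (the chain cannot move; the summary is
flagged degenerate). Use the r1 null when the question is "more nested than
random given richness", the swap null when margins must be held fixed.

## Spatial and environmental predictors

**PCNM.** Pairwise Euclidean distances are truncated at a threshold (by
default the longest minimum-spanning-tree edge, which keeps the network
connected); larger distances are replaced by 4x the threshold; the
principal coordinates of the Gower-centred matrix are extracted and the
positive-eigenvalue eigenvectors (unit length, mutually orthogonal,
centred) serve as predictors, broadest spatial scale first — on an
equidistant transect eigenvector j shows the classical sinusoid with j sign
changes. Coordinates are treated as planar; `project_lonlat` offers an
equirectangular pre-projection adequate for single-estuary extents
(kilometres). Negative- and zero-eigenvalue vectors are computed but never
exposed as predictors. Replicate sites of one station may share
coordinates; only fully coincident point sets are rejected.

**Environment.** Variables (salinity plus eight grain-size fractions; no
sum constraint is imposed on the fractions) are z-score standardized
(sample sd, n−1). Collinearity is pruned iteratively: VIF_k = 1/(1−R²_k)
from regressing predictor k on the others; while any VIF ≥ the threshold
(default 3) the largest is dropped (exact collinearity counts as infinite
and goes first); the report records removal order and final VIFs. VIF is
computed on the predictor matrix alone, which equals the
constrained-ordination VIF for a common predictor set.

## RDA and variation partitioning

Community matrices are Hellinger-transformed (square root of site-relative
abundances) so Euclidean-based ordination is appropriate for composition
data. RDA fits the transformed matrix on a predictor set by least squares;
R² is the fitted sum of squares over the total, adjusted by the Ezekiel
formula `1 − (1−R²)(n−1)/(n−m−1)` with every column (e.g. each spatial
eigenvector) counted as one predictor. Partial RDA residualizes both sides
on the conditioning set first. Permutation tests are Freedman–Lane: rows of
the conditioned community residuals are permuted and the pseudo-F
recomputed; p = (exceedances + 1)/(permutations + 1) with 999 permutations
by default.

**Forward selection** is gated by a significant global test on the full
predictor set, then admits at each step the candidate adding the most
explained variance, only if its conditional permutation p < alpha *and* the
cumulative adjusted R² stays at or below the global model's (the
double-stopping criterion, matching vegan's `ordiR2step`). Because adding a
pure-noise predictor leaves the adjusted R² unchanged in expectation, the
global bound can legitimately block even a strong lone predictor in about
half of such cases — selection then returns empty with the reason recorded.

**Three-way partition.** Adjusted R² is computed for the seven unions of
the environmental, spatial and temporal sets (time = sampling-occasion
dummies, first level dropped; duplicated or linearly dependent columns in a
union are removed before fitting). The eight fractions (three pure, three
pairwise-shared, one triple, one residual) follow by inclusion–exclusion
and sum to one identically (asserted to 1e-10). Pure fractions are tested
by partial RDA conditioned on the union of the other two sets; shared
fractions are not testable. Negative fractions are reported as computed —
truncating them would break the identity; display layers may floor at zero.
An empty set fixes its fractions at zero with a note. All fractions agree
with vegan's `varpart` to 1e-8 on frozen fixtures.

## Synthetic data

`generate_structure` realizes the idealized structures on 20 sites x 40
species by default at fill 0.5, emitting rows in a recorded random
permutation (gradient position preserved in station labels) so analyses
must recover the order by ordination:

* **nested** — ranges anchored at one gradient end; lengths drawn from
  three cluster values (clumped loss), uniformly (random loss), or from a
  balanced lattice (hyperdispersed loss);
* **clementsian** — up to four groups with identical range endpoints,
  group blocks staggered along the gradient;
* **gleasonian** — staggered end-to-end tiles of the target length with
  independent integer jitter of ±0.4x the length on each boundary: boundary
  positions land quasi-uniformly (non-clumped) while ranges stay dispersed
  enough for positive turnover;
* **evenly spaced** — the same staggered tiling without jitter; any jitter
  below half the sub-site lattice spacing collapses under integer rounding,
  so boundary evenness is exact and randomness enters through the
  species-to-range assignment and the row permutation;
* **checkerboard** — mutually exclusive species pairs splitting a shared
  site pool (zero co-occurrence at every site, preserved by construction),
  then a hill climb perturbs presences to maximize the embedded absences of
  the re-ordinated matrix. This optimization is the model: a checkerboard
  metacommunity is definitionally one with more interruptions than chance
  under its best gradient ordering, and random disjoint splits alone are
  statistically indistinguishable from the fixed-row null (their
  complementary structure cancels in the statistic);
* **random** — iid Bernoulli(fill).

Each generator's output is classified as its own structure (or quasi-
variant) in ≥ 90% of seeds at the default sizes with 200 null iterations.

`generate_gradient_community` draws a multi-campaign estuary survey:
stations equally spaced on a line (default 10 stations x 2 replicate sites,
1 km spacing), salinity linear from 40 at the seaward station to 0.5
upstream, eight sediment fractions as a softmax of station-level AR(1)
latent series (autocorrelation 0.7, percentages summing to 100), species
optima uniform over the salinity range with Gaussian niches (sd 6 salinity
units, peak expectation 20 individuals), multiplicative log-normal period
effects (sd 0.3, default 4 periods) and Poisson counts. Defaults were
chosen once as field-realistic magnitudes: niche breadth ~15% of the
gradient yields ranges spanning several stations; peak abundance 20 gives
presence probabilities near one at the optimum and a soft range edge.
`generate_study` assembles the three-estuary design (10x2x4, 10x2x4,
11x2x5 = 270 site-samples, 13 campaigns).

What the generator does *not* emulate: taxonomic identity and richness of
real estuaries, zero inflation beyond Poisson (an overdispersion switch is
out of scope), environmental effects other than salinity on abundances
(sediment series are spatially structured noise), and asymmetric species
pools. The last point matters for interpretation: with optima uniform over
the gradient the expected structure is Gleasonian/evenly-spaced turnover —
the textbook prediction for a continuous gradient — and that is what the
classifier reports on the synthetic bundle. Real estuarine data lean
nested/quasi-nested because the species pool is largely of marine origin,
anchoring ranges at the seaward end; passing tests on the synthetic bundle
therefore demonstrate recovery of gradient structure, not of nestedness per
se.

## Pipeline

The `metacom` CLI (and `RunConfig`-driven functions) runs EMS + NODF per
estuary x period campaign, variation partitioning per estuary (periods
pooled into site x period rows, occasion dummies as the temporal set; PCNM
computed on unique site coordinates and repeated across periods), and
sample-based rarefaction per estuary (random addition order; the endpoint
equals pooled richness by construction). Defaults mirror standard practice:
1000 null iterations, 999 permutations, alpha 0.05, VIF threshold 3,
site-level rows (station pooling available). Every stochastic step derives
its seed from the single run seed via CRC-tagged seed sequences, so reruns
are byte-identical; degenerate campaigns are reported and skipped, and all
drops/broadcasts are logged.

The bundled verification battery (`scripts/acceptance.py`, tests) uses 100
seeds per generator at 200 null iterations and 50 gradient-community seeds
at 199 selection permutations — sizes at which the binomial error of the
reported rates is a few percent while the full battery runs in minutes on a
single core.

## Known limitations

* The EMS framework evaluates only the first ordination axis; metacommunity
  structure along secondary gradients is out of scope.
* The normal-approximation p assumes an approximately Gaussian null; for
  very small matrices use `empirical_p=True`.
* The chi-square clumping test is asymptotic; with few boundaries
  (F < ~20) its calibration degrades, which is inherent to the method.
* The fixed-fixed NODF null cannot detect nestedness that is fully encoded
  in the margins (see above); this is a property of the null, not a defect.
* Forward selection inherits the known conservatism of the global
  adjusted-R² bound.
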