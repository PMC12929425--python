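# Methods

This note records the models, conventions and numerical choices behind
`plonet`, and what the synthetic validation does and does not establish.

## Data model and validation

A community is a labelled non-negative matrix of visit counts, rows =
plants, columns = pollinators (a transpose flag accommodates the opposite
layout). Validation drops all-zero rows and columns — never-observed taxa
occur in published matrices — with a logged warning, and never alters a
retained weight. Weights are treated as visit counts throughout: the
presence/absence threshold is strictly `> 0`, and non-integer weights are
rounded half-up before null-model marginals are computed. Trait tables carry
explicit `unknown` levels (blank cells are mapped to `unknown` at parse
time; unrecognized tokens are an error). Species matching between networks
and the trait table is exact after whitespace/case normalization; fuzzy
taxonomic resolution is deliberately out of scope.

## Structural indices

**Connectance** is computed on the binarized matrix; nestedness and
modularity on the weighted matrix (the module-detection algorithm targeted
here is a weighted one; a config switch `modularity_weighted=False`
binarizes first for sensitivity analysis).

**Weighted NODF.** An ordered row pair (i, j) contributes only when row i's
weighted marginal total strictly exceeds row j's (ties contribute zero);
the contribution is `100 · #{k : 0 < w_jk < w_ik} / #{k : w_jk > 0}`.
Column pairs are scored on the transpose and the index is the mean over all
unordered row and column pairs. Note a convention caveat: some
implementations in circulation gate pair eligibility on *binary fill*
rather than weighted totals; the two definitions diverge on matrices where
fill order and total order differ. The tests therefore validate against an
independent loop-based implementation of the definition above, not against
third-party code.

**Modularity.** Barber's bipartite Q. The default optimizer runs 10 seeded
restarts (restart count is a free choice; it is configurable and recorded)
of a two-phase heuristic: (1) side-wise best-gain relabelling — a vertex's Q
contribution depends only on the opposite side's labels, so each side is
updated in one exact coordinate-ascent sweep; ties break to the smallest
label index for reproducibility, and a vertex whose best gain is negative
takes a fresh singleton label; (2) greedy module merges accepted while Q
increases. If the best restart lands below zero the single-module partition
(Q = 0 exactly, an algebraic identity) is returned instead. The exhaustive
method enumerates set partitions of the smaller side only and assigns each
opposite vertex to its best-gain group: because Q decomposes over modules as
`(W_kk − R_k C_k/m)/m` and opposite-side vertices do not interact, this
equals the maximum over all vertex set partitions; a guard refuses networks
above 12 vertices.

## Extinction and robustness

The extinction curve starts at (0, 1); after each plant removal a pollinator
survives iff it retains a positive interaction; validated networks reach
(1, 0) exactly. Robustness is the trapezoid area over the n+1 points —
endpoint conventions differ across the literature, so this one is fixed for
determinism; the n×n one-to-one network then scores exactly 0.5 under every
order, a convenient closed form. Random policies draw 100 orders by default
(a free choice; configurable). Ploidy-targeted policies remove the targeted
cytotype first, in seeded random order within blocks; unknown-ploidy plants
are grouped with the non-targeted block, so targeting touches only what is
classified (logged).

## Null standardization

Delta transformation subtracts the null mean (no z-scoring): `Δ = raw −
mean(index over nulls)`. Null matrices preserve dimensions and both marginal
vectors exactly, drawn by Patefield's algorithm (`scipy.stats.random_table`)
— the classic fixed-marginal contingency-table sampler, under which each
table carries its hypergeometric (independence-conditional) probability
rather than uniform weight. A connectance-preserving alternative (`fill`:
shuffle the positions of the positive cells) sits behind a flag because the
appropriate null family is a genuine modelling choice; the variant used is
recorded in output metadata. Default replicate count is 100 (free choice,
configurable). A replicate on which an index is undefined is redrawn with a
capped retry count.

## Cohort filters and trait frequencies

%PP, %SC and %Restrictive are each computed over the species with known
state for that trait; a frequency is undefined when its denominator is
empty. Restrictiveness is binned {unrestrictive, low} → not restrictive,
{moderate, high} → restrictive. Retention requires ≥ 6 pollinator taxa, ≥ 6
ploidy-classified plants, ploidy coverage ≥ 1/3 (an exact rational
comparison, so 6 of 18 passes an "at least 33%" rule), and available
climate; the path-analysis subset additionally requires at least some data
for %SC or %Restrictive. A predictor counts as available for a network when
its frequency is defined (n_known ≥ 1); the minimum is configurable since
a stricter per-network coverage rule is defensible.

## Regressions and spatial check

Univariate OLS per predictor × index on that predictor's complete cases (so
n varies by predictor, maximizing power). Reported: Pearson r, the slope,
and `t = r√(n−2)/√(1−r²)` with its two-sided p — the t statistic doubles as
the standardized-effect column in the summary table. Precipitation
covariates are transformed `ln(x+1)` (precipitation of the warmest quarter
can be 0; natural log; the offset is a choice the source scale does not
dictate), network size as `ln(plants + pollinators)` (size measure
configurable). Moran's I uses row-standardized inverse great-circle-distance
weights, expectation −1/(n−1) and the standard normal approximation;
coincident points receive the largest finite weight. SAR-type corrections
are out of scope; the test flags when they would be warranted.

## Piecewise SEM

Five equations estimated locally by OLS, each on its own complete cases —
chosen because trait coverage is very uneven (mating-system data is sparse),
and an all-variables complete-case fit wastes most networks; the strict
variant is available via `complete_cases_only`. Standardized coefficients
use the sample SDs of each equation's complete cases. The d-separation basis
set contains one claim per non-adjacent pair, conditioned on the union of
the pair's parents and tested as the added-term p with the later variable in
topological order as response (the standard convention; only finite-sample p
is affected). The base diagram yields 4 claims (df = 8), none involving the
focal index, so Fisher's C is shared across the four index models on the
same records. Robustness variants (`bio10`, `both`, `no-rs`, `no-sc`) are
config presets. Effects decompose over directed paths; `total = direct +
Σ indirect` holds exactly by construction.

## Synthetic generator

Pollinators sit at uniform positions on [0, 1]; plant i has niche centre
c_i ~ U(0, 1) and breadth σ0 (diploid) or σ0·κ (polyploid); visit counts are
Poisson with mean `λ·exp(−(u−c)²/2σ²)`. κ > 1 is the broadened-polyploid-
niche scenario, κ < 1 the narrowed one, κ = 1 the null. Per network, %PP
follows a logit model on standardized log precipitation seasonality;
per-plant self-compatibility and restrictiveness follow logits with negative
ploidy coefficients (polyploid-rich communities have fewer self-compatible
and fewer restrictive-flowered species); seasonality also narrows niches and
shrinks communities, so climate reaches both the plant variables and the
indices. Missingness masks ploidy/mating/restrictiveness at rates 0.30 /
0.79 / 0.34, mirroring the sparse coverage of real trait compilations
(mating system is by far the thinnest). Community sizes are drawn to average
roughly 16 plants and 45 pollinators. Defaults κ = 3, σ0 = 0.10, logit slope
0.8 were calibrated once so that the broadened-niche scenario produces
%PP–Δnestedness associations of roughly the magnitude seen in real cohorts
(r ≈ 0.15–0.25) — with κ near 1 the mechanism is too weak to rise above
sampling noise, and with very small σ0 the nestedness response inverts, a
reminder that the kernel's geometry, not just κ, shapes the structural
signal. A single study seed spawns per-network seed sequences, so any
network is reproducible in isolation, and draws failing the retention
filters are replaced (capped retries), so generated studies pass the filters
by construction.

**What the generator does not emulate:** phenology and temporal turnover,
within-community spatial structure, pollinator population dynamics, shared
species across networks (every synthetic species is network-local),
taxonomic resolution artefacts, and sampling-effort bias. Passing tests
therefore establish that the pipeline recovers the structure this mechanism
encodes at these sizes — not that real cohorts satisfy the model.

## Test and validation sizes

The suite validates indices against brute-force oracles on hundreds of
small random networks (exhaustive modularity on ≤ 8–12 vertices, where full
partition enumeration is feasible), checks Fisher's C type-I calibration on
1,000 model-true simulations at the path-analysis cohort size (n = 313),
checks coefficient recovery at n = 5,000, and runs the niche scenarios as
10 studies × 120 networks (directional consistency) and 500 studies × 40
networks (type-I rate, with ploidy decoupled from climate so the null truly
holds). These sizes are the package's chosen validation scale; the
generator and pipeline run unchanged at larger ones.

## Known limitations

- The label-propagation optimizer is a heuristic; it attains the exhaustive
  optimum on ~99% of small random networks in testing but carries no
  guarantee at realistic sizes.
- Patefield sampling is not uniform over tables with fixed marginals; if a
  uniform null is intended the delta means will differ slightly.
- The d-separation test assumes linear-Gaussian claims; heavily skewed
  frequencies near 0/1 strain that assumption.
- Moran's I uses the normal approximation, anti-conservative at very small
  n; the permutation alternative is easy to add if needed.
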