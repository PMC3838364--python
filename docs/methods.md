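# Methods

This note documents the models, the numerical choices, and what the
synthetic scenarios do and do not establish about real survey data.

## Gower dissimilarity (traits_distance)

For species *i, k* and traits *j* with positive weights *w_j*:

d(i,k) = Σ_j w_j δ_ijk s_ijk / Σ_j w_j δ_ijk,

where δ_ijk = 1 iff trait *j* is non-missing for both species
(pairwise deletion), s_ijk = |x_ij − x_kj| / range_j for quantitative
and ordinal traits (range over the non-missing values of the input
table, not a theoretical range) and the 0/1 mismatch for nominal and
binary traits. Ordinal traits are treated as ranks and
range-normalized like quantitative ones (classic Gower; no Podani
correction). Default weights are 1. A zero-range ordered trait
contributes 0 with a warning; a species pair with no comparable trait
is an error, never an imputed 0 — silent imputation would place the
pair at maximal similarity for no reason. Output is symmetric, zero
diagonal, bounded in [0, 1].

## UPGMA and trees (trees)

True (size-weighted) average linkage: after merging clusters A, B,
d(AB, C) = (|A| d(A,C) + |B| d(B,C)) / (|A| + |B|); node heights are
half the merge dissimilarity, so the dendrogram is ultrametric by
construction (checked to 1e-9). When several pairs tie at the minimal
distance, the pair whose lexicographically smallest member label sorts
first is merged; rows are sorted by label first, so the result is
independent of input row order. Zero-length branches are allowed
(co-identical species). Newick is read through dendropy with extra
validation (duplicate tips, negative lengths, parenthesis balance with
position) and written with 12-significant-digit lengths. Cophenetic
distances are tip-to-tip path sums.

## Originality (originality)

*Equal-splits.* Walking from the root, each edge's length is divided by
the child count of every node passed below it; a tip's score is the sum
along its path. Polytomies divide by the actual child count; a root
with a single child divides by 1 (no split) with a warning. The scores
sum to the total branch length — this conservation identity is used as
a standing oracle in the tests.

*QE weights.* The QE score vector is the maximizer of Rao's quadratic
entropy p'Dp over the probability simplex. For ultrametric D (every
UPGMA dendrogram; usual chronograms) the objective is concave on the
simplex and the maximizer is unique. The solver is an iterative
active-set method: solve the equality-constrained stationarity system
2 D_SS p = λ1, 1'p = 1 on the current support, drop the most negative
coordinate while any is negative, then verify the KKT condition
2(Dp)_j ≤ λ for excluded species and re-admit the worst violator;
stationarity tolerance 1e-10. Exhaustive enumeration of all supports is
kept in the test suite as an independent oracle for small instances
(≤ 6 species, coordinate agreement 1e-6) rather than used as the
production path, where the iterative method is exact anyway and scales
past the ~26-species regime this package targets.

*Proportions.* Scores are optionally normalized to sum to one, the
convention used when comparing species profiles across trait sets.
Both raw and proportion scales are exposed because quoted originality
values in the literature mix the two.

*Species-addition stability.* Scores are recomputed after adding random
subsets of extra species; extended scores of the shared species are
regressed on the base scores by simple least squares and the
coefficient of determination reported on a 0–100 scale. Note that
adding even an exact duplicate of a species halves that species' own
equal-splits score (its pendant branch becomes a shared split) and
shifts the others slightly through the size-weighted linkage — rank
stability among unaffected species is the meaningful invariant.

## Specialization (specialization)

Sites are standardized on the four abiotic variables, clustered by
k-means (k = 7 by default), then rebalanced: members of over-full
classes move to the under-full class with the cheapest centroid-distance
penalty until no class exceeds ⌈n/k⌉ + slack. The paper-level goal is
equal class sizes (this also absorbs headwater oversampling); the
specific algorithm (k-means + capacity reassignment) is this package's
choice, deterministic under a fixed seed.

SSI is the coefficient of variation of a species' class-mean densities.
Class means average over all sampling occasions (site-year pairs) in
the class, with absences counted as zero density — dropping absences
would make the CV meaningless. The standard deviation uses the sample
(n−1) convention, matching common usage of the CV in the
specialization-index literature with small k; `ddof=0` switches to the
population convention. Bounds: 0 (perfect generalist) to √k
(single-class occupant, sample convention). Species with zero total
density are excluded with a warning.

## Community aggregation (community)

Index per occasion = Σ a_i X_i / Σ a_i over scored species. Unscored
species are removed from numerator and denominator and surfaced through
a coverage fraction (scored density / total density); occasions under
the coverage threshold (default 0.5) or with no scored density are
flagged, never silently dropped. Densities (counts per unit effort) are
the intended weights when effort varies; raw counts are acceptable at
constant effort. Intraspecific trait variation is out of scope.

## Sensitivity pipeline (sensitivity)

Base model: index ~ fixed effects + (1 | site), fixed effects drawn
from {year (centered), x, y, watershed, year interactions with the
spatial terms}. Candidates for AIC selection default to
{year} × {x+y, watershed, x+y+watershed} × {with/without year
interactions}; selection uses ML fits on identical rows, ties broken
toward fewer parameters. Final coefficients are REML; the ML/REML split
is the standard-compatible choice where the source workflow is silent.
If the random-intercept variance collapses below 1e-8 of the residual
scale the fit falls back to OLS with a warning. Rank-deficient designs
are rejected with the aliased columns named.

Land-use classes enter reference-coded against the natural class
(Forest), whose coefficient is structurally zero. The family of class
p-values is adjusted by Benjamini–Yekutieli:
adj_(i) = min_{j≥i} min(1, p_(j) · m · c(m)/j), c(m) = Σ_{j≤m} 1/j,
valid under arbitrary dependence and elementwise ≥ the
Benjamini–Hochberg adjustment. The R² proxy is the adjusted R² of the
identical fixed-effects model refit without the random intercept
(no R² exists for the mixed model itself).

Classification variants: CLC5 (Forest, Meadow, Farming, Mix, Urban),
EUROWATER6 (+ Intensive Urban), ONEMA7 (+ Intensive Farming), listed in
artificialization-gradient order. An index is flagged *robust* iff all
significant (BY-adjusted p < 0.05) class effects across the variants
carry one common sign; with a single variant or no significant effect
robustness is undetermined. Watershed consistency refits per watershed
(watershed terms removed from the candidates), skipping watersheds
below a minimum site count, and summarizes significant coefficient
signs per class. A region exclusion option drops flagged sites before
any fitting and is exactly equivalent to fitting on the complement.

## Synthetic scenarios (synthetic_data)

Defaults emulate a national electrofishing network at desk scale: 26
species, 300 sites × 5 years, lognormal densities (log-noise sd 0.5 per
occasion × species), per-species occupancy 0.9, species baseline
log-abundances N(2, 1), site random effect sd 0.01 on the index scale.

*Traits.* Species occupy positions in a 2-D latent functional space;
every trait (14 columns by default: 7 quantitative — half exponentiated
for body-size-like skew — 3 ordinal, 2 nominal, 2 binary) is a noisy
linear readout of that position (readout noise sd 0.5 per trait).
Correlated traits give dendrograms a reproducible shape, as real trait
compilations do; independent columns would make originality rankings
pure noise. Optional missingness is uniform at a configurable rate.

*Trees.* Sequential random coalescence with exponential waiting times;
ultrametric by construction.

*Abiotic variables.* Driven by a Beta(0.8, 1.6)-skewed upstream factor
(headwater oversampling): upstream sites are colder, higher, steeper,
and low on the longitudinal gradient.

*Surveys with injected effects.* Site targets are baseline + class
effect + N(0, σ_site²); species log-densities are tilted along the
score axis by the t solving E[Σ aX/Σ a] = target, where the expectation
uses a delta-method correction for the lognormal noise and occupancy
thinning (without it, recovered coefficients are biased upward by tens
of percent). Because a weighted-mean index is bounded by the score
range, targets are truncated just inside it (2% margin; binds only in
extreme tails). Effects beyond the score range raise an error.

What passing simulations show: the pipeline controls the family-level
type-I rate under a null land-use effect, recovers an injected −0.02
urban shift in sign and magnitude at 300 × 5 scale, and flags a
uniformly negative gradient robust across classification variants.
What they do not show: behavior under spatially autocorrelated
residuals, confounding between land use and the abiotic gradient,
effort heterogeneity, or species interactions — none of which the
generator emulates.

## Problem sizes in tests and scripts

Simulation-based checks use 100 replicates at 300 sites × 5 years (50
in `scripts/acceptance.py`), small-instance oracles up to 6 species for
the QE program, and 100 random trees of 8–64 tips for the conservation
identity — sizes chosen to bracket the ~26-species, multi-hundred-site
regime the methods target while keeping a full run in minutes.
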