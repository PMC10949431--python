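# Methods

This note documents the models and procedures `microtempo` implements, the
choices made where the design was genuinely open, and what the synthetic
validation does and does not establish about real data.

## The study design being analyzed

The pipeline targets longitudinal amplicon surveys of host-associated
microbial communities in a common garden: ten clonally propagated host
genotypes (eight *Populus trichocarpa*, two *P. deltoides*) in three blocks,
sampled at eight dates spanning two years and four seasons (winter, spring,
summer, fall in each year, matched dates roughly one year apart), with three
to five replicate plants per genotype per date, in three habitats (leaf
endosphere, root endosphere, rhizosphere) and two microbial domains
(bacteria/archaea, fungi).  Leaf samples do not exist in winter because the
host is deciduous; every stage tolerates the resulting six-date leaf design.
The common-garden layout removes spatial environmental variation, and clonal
replication removes host genetic variation within genotype, so temporal
terms (season, year, season × year) carry the signal of interest.

## Normalization

**SRS (scaling with ranked subsampling).** Each sample's counts are scaled
by `c_min / total`; integer parts are kept and the remaining units (always
fewer than the number of taxa) go one each to the largest fractional parts,
ties broken uniformly at random under a caller-supplied seed.  Unlike
multinomial rarefaction this is deterministic up to tie-breaking, preserves
within-sample rank order, and makes every column sum exactly `c_min`.  The
default target is the observed minimum sample total, matching
subsample-to-minimum practice; shallower samples are dropped with a warning
rather than failing the run.  Tie handling is randomized-but-seeded because
the procedure's definition permits any tie rule and reproducibility matters
more than the (immaterial) choice among tied taxa.

**CLR.** y_i = ln(x_i + pc) − mean_j ln(x_j + pc), pseudocount default 1 on
raw counts.  The network stage consumes CLR of *non-subsampled* tables:
depth normalization is unnecessary there because CLR already removes the
per-sample scale, and subsampling would only discard information.

## Diversity and dissimilarity

Hill numbers ^qD = (Σ p_i^q)^{1/(1−q)}; q = 1 is computed as
exp(−Σ p_i ln p_i) (the limit form) rather than by numerically approaching
q → 1.  ^qD is non-increasing in q, which the tests assert per sample.
Bray-Curtis is computed on SRS-subsampled counts (equal column sums make it
equivalent to the proportion-based form).  A pair of all-zero samples has an
undefined denominator and is rejected.

## Permutational multivariate inference

All partitioning happens on the Gower-centered inner-product matrix
G = −½·C·D²·C.  Sums of squares are traces of projector-weighted G, so
terms + residual = total holds exactly on every run.

**PERMANOVA.** Sequential (Type-I) SS in caller order — the recommended
order is season, year, season:year, species, mirroring how temporal terms
take precedence in the design — via incremental orthonormal bases of the
cumulative design; pseudo-F uses the residual mean square; p-values use the
(1 + exceedances)/(1 + permutations) convention so they are never exactly
zero.  Strata constrain permutations within levels of a grouping factor
(genotype, for the repeated-measures check); an exact mode enumerates all
admissible permutations (guarded to ≤ 2 × 10⁶) and reports the enumeration
p including the identity.  Marginal (Type-III-style) tests are available
through dbRDA's term tests.

**PERMDISP.** Samples are embedded by principal coordinates; negative
eigenvalues of G (inevitable for Bray-Curtis) become imaginary axes, and the
distance of a sample to its group centroid is √max(d²_real − d²_imag, 0).
The test is the parametric one-way ANOVA F on those distances, with group
centroids (not spatial medians); permutation-p variants are out of scope.

**dbRDA.** McArdle–Anderson direct approach: the constraint design is
centered, its hat matrix H gives constrained inertia tr(HGH), and ordination
axes are eigenvectors of HGH.  No square-root (Lingoes/Cailliez) correction
is applied; negative inertia is reported and a warning fires when its
magnitude exceeds 5% of total.  Aliased design columns are dropped with a
warning.  Per-term tests are marginal (remove-one), permuting G.  On
Euclidean distances the constrained fraction equals classical redundancy
analysis exactly, which the tests verify.

**Climate PCA.** Rows are the daily records in the 7-day window before each
sample date; the six variables (tmin, tmax, day length, shortwave radiation,
precipitation, vapor pressure) are min-max scaled to [0, 1] across retained
rows, and PCA runs on the covariance of the scaled matrix — the scaling
already homogenizes ranges, so correlation-matrix PCA would double-correct.
Per-date mean scores (PC1, PC2) feed dbRDA as climate constraints.

## Dissimilarity–time decay

The decay table holds, for every genotype and unordered date pair, the mean
Bray-Curtis over that genotype's cross-date sample pairs (within-date and
cross-genotype pairs are excluded; averaging within genotype absorbs the
pseudo-replication of repeated sampling).  The fit is OLS of mean
dissimilarity on Δt, with the slope reported per 365 days (and per day),
because printed slopes of this magnitude are naturally read on an annual
scale.  The primary confidence interval uses a genotype-clustered
covariance: rows of the decay table reuse the same samples across date pairs
within a genotype, and the classical iid interval measurably undercovers the
planted slope (≈ 90% instead of 95% in simulation); the classical interval
is retained in `ols_*` fields.  A random-intercept-per-genotype mixed model
(ML) provides the robustness check on the same fixed effect.

The environmental analogue tabulates Euclidean distances between scaled
7-day window means for every date pair.  Rather than fitting a smoother, an
oscillation diagnostic — the Pearson correlation between distance and
|sin(πΔt/365.25)| — summarizes whether environmental dissimilarity cycles
annually (diagnostic near 1) instead of accumulating.

## Core community

An ASV is core when its occupancy (fraction of samples with a nonzero
count) reaches 70% at one or more time points; the threshold is inclusive
(≥).  Occupancy is computed on the subsampled table because occupancy is
depth-sensitive; a flag allows raw counts.

The contribution of the core set to turnover is, per sample pair,
C = BC_core / BC_all with BC_core = Σ_core|x−y| / Σ_all(x+y): the numerator
is core-restricted but the denominator is the full community, so C ∈ [0, 1]
and contributions of disjoint ASV sets are additive (the alternative —
recomputing Bray-Curtis on the core sub-table, which changes the
denominator — is not additive and can exceed 1; the chosen form is the one
consistent with "contribution to overall dissimilarity").  Pairs with zero
total dissimilarity are excluded with a warning; within- vs among-season
pair classes are tagged when metadata is supplied.

Core groups: mean relative abundance per ASV per time point (averaged over
that date's samples), standardized per ASV to Z-scores using the population
SD (n divisor — documented so profiles are exactly reproducible), pairwise
distance 1 − Pearson r (in [0, 2]), complete-linkage agglomerative
clustering.  The number of groups is the smallest k at which the gain in
variance explained (1 − within-group SS / total SS of the Z-profiles) from
k to k+1 falls below 5% (configurable), scanning k = 1..8.  Variance
explained is computed on profiles, not on distances.  Constant-temporal
profiles cannot be standardized and are excluded with a warning, reported
separately.

## Co-occurrence networks

Inputs are the non-subsampled tables of both domains over their shared
samples, each prevalence-filtered (ASVs in < 20% of samples removed;
exactly 20% is retained) and CLR-transformed per domain before
concatenation.  Neighborhood selection runs one lasso per node over a
shared geometric penalty grid (20 points, λ_max = the largest absolute
off-diagonal correlation of the standardized CLR matrix, λ_min/λ_max =
0.01).  StARS draws 20 subsamples of size ⌊10√n⌋ (capped at n−1) without
replacement, computes per-edge selection frequencies θ̂ and total
instability D(λ) = mean over node pairs of 2θ̂(1−θ̂), monotonizes D by its
running supremum from λ_max downward, and keeps the largest λ with D ≤ β
(β = 0.05).  Edges are symmetrized by the OR rule by default (AND
available); edge signs come from the lasso coefficients (summed across the
two directed regressions, falling back to the CLR correlation sign on exact
cancellation) and are recorded but unused in centrality.  Degree and
betweenness (Brandes, unweighted, unnormalized) come from the final graph.
Subsample count, β, the grid and the symmetrization rule are all
configurable because reasonable analyses differ here; the defaults follow
the conventions of stability-selected sparse graphical models at desk
scale.

Hubs are nodes at or above the 90th percentile (inclusive nearest-rank, so
ties at the cutoff qualify) of *both* degree and betweenness that are also
core members and have mean relative abundance ≥ 0.1% on the non-subsampled
table of their own domain.

## Guilds and factorial ANOVA

Guild assignment is a lookup-table join: taxon names at any rank map to
guilds, the most specific matching rank wins (genus before family before
order …), no match yields "unclassified", and confidence strings pass
through unfiltered.  The curated guild database itself is not shipped; a
user-supplied or generated table is the interface.

The factorial ANOVA uses sequential Type-I SS in the order season, year,
species with all interactions (the unbalanced 3–5-replicate design makes
order matter; the temporal-first order matches the design's logic).
Tukey HSD uses the studentized-range distribution with the Tukey–Kramer
correction for unequal cell sizes; compact letters come from the maximal
cliques of the non-significance graph, which guarantees cells sharing a
letter are never significantly different and every non-significant pair
shares one.

## Synthetic data: what it emulates

Latent log-abundance of ASV i in sample s at date t:

    η_is = base_i + A_iy·cos(2π(doy(t) − φ_i)/365.25)·[seasonal_i]
         + b_i·t_days·[drifting_i] + g_i(genotype(s)) + ε_is

Counts are multinomial per sample with softmax(η) composition and lognormal
depth; sparsity arises from finite depth (≈ 55% zeros at the defaults), not
from an explicit zero-inflation component.  ε is multivariate normal with a
sparse precision matrix built from the planted edge list (off-diagonal
−ρ, diagonally dominant), so planted edges are conditional dependencies of
exactly the kind the network stage estimates.

Key defaults and why:

- `dates` — the study's printed eight sample dates, so Δt structure
  (~100–600 days) matches the real design, including the ±12-day mismatch
  between years.
- `seasonal_frac = drift_frac = 0.3`, `season_amplitude = 1.0` (log scale).
- `interaction_sd = 0.8`: per-ASV year-specific modulation of the seasonal
  amplitude.  With a fixed amplitude both years, the design produces almost
  no season × year interaction — but year-dependent seasonal patterns are a
  central feature of the system being emulated, so the generator plants
  them explicitly.  At 0.8 the interaction is present and detectable in
  every seed tried (R² ≈ 0.015–0.05 at n ≈ 320).
- `drift_rate = 0.003`/day with random sign per drifting ASV: produces
  decay slopes ≈ 0.05–0.13 per 365 d at the defaults, the magnitude range
  such surveys report, and keeps the directional trend from being swamped
  by the year-modulated seasonal term.
- `genotype_sd = 0.25` (small — host effects in this system explain only a
  few percent of variation), `noise_sd = 0.5`, `base_sd = 2.5` (wide
  abundance spectrum; gives realistic sparsity and a core of ≈ 30–40% of
  taxa), depth lognormal(8.5, 0.3) ≈ 5,000 reads median.
- `network_strength = 2.5`: planted partial correlations ≈ 0.3–0.45 —
  strong, genuinely "detectable" direct associations; weaker values sit at
  the compositional noise floor of CLR-transformed multinomial counts and
  no method would recover them at n ≈ 200.

Climate is an annual sinusoid per variable (variable-specific phase and
amplitude, period 365.25 d) plus small daily noise, with tmin = tmax minus
a positive offset; identical calendar dates across years differ only by
noise, emulating a site with strongly year-correlated climate.

**Planted-truth oracle for the decay slope.** The estimand of the decay
regression is E[BC between two same-genotype samples] as a function of Δt
*under the full generative process* — noise and finite depth compress the
latent signal nonlinearly, so the noise-free latent slope overstates the
target by roughly threefold and is not the right truth.
`expected_decay_slope` therefore computes the expectation by Monte-Carlo
enumeration (per date pair, many within-genotype sample pairs drawn from
the model, conditional on the dataset's realized genotype effects, compared
as proportion vectors at realized lognormal depths) and regresses it on Δt.
Measured CI coverage of this truth is 19/20 seeds with and without drift.

**What passing tests do not show.** The generator draws multinomial counts
from a softmax composition: it has no taxon-specific overdispersion beyond
the planted lognormal depth and MVN noise, no zero inflation, no
phylogenetic structure in the lineages, and its guild table is a random
genus → guild map.  Recovery results therefore demonstrate correctness of
the statistical machinery under a plausible generative model, not
performance guarantees on real sequencing data, where compositional
artifacts, contamination and taxonomic misassignment add error modes the
simulation does not contain.

## Numerical choices and degenerate inputs

- Rank decisions (design matrices, aliased constraints) use an SVD with a
  relative tolerance; aliased columns drop with a warning.
- Permutation-F comparisons use a 10⁻¹² slack so exact ties count as
  exceedances.
- Identical Z-profiles are detected with a relative total-SS tolerance so
  the group count collapses to 1 instead of chasing float noise.
- Zero-variance samples, all-zero sample pairs, single-level factors,
  singleton dispersion groups, sub-depth samples and empty λ grids all
  raise (or warn-and-drop) as documented per function.
- One known aliasing effect, verified by the oracle: with these eight
  unevenly spaced dates, a purely seasonal community yields a small
  *negative* expected decay slope (≈ −0.007 per 365 d), because long-Δt
  pairs are disproportionately cross-season.  The fitted slope tracks that
  expectation; it is a property of the design, not an estimator bias.

## Problem sizes

The test suite and the reproducibility script run the full design at 200
ASVs per community (≈ 320 samples), recovery experiments at 20–150 ASVs,
null calibrations at 500 replicates × 199 permutations, and networks at 30
nodes × ≈ 240 samples — sizes chosen so each experiment's Monte-Carlo error
is small relative to the property it checks while the whole suite stays
desk-scale.
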