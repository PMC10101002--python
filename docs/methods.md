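# Methods

This note documents the models implemented in `fermnet`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations.  Nothing here reports an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Input model

All analyses operate on taxa × sample abundance tables (integer read
counts or relative abundances), one per domain (bacteria via 16S,
fungi via ITS).  Because the two libraries are sequenced and normalized
separately, relative abundance is computed *within* each domain by
default: in a merged table, bacterial columns sum to 1 and fungal columns
sum to 1 (a global-normalization mode exists).  Sample alignment is by
case-sensitive ID match, never by position, and missing values are
rejected: a non-detection must be an explicit zero, because "not measured"
and "not detected" have different consequences for prevalence filtering.

Taxon filtering keeps taxa present in strictly more than 20 % of samples
with mean relative abundance strictly greater than 0.01 % (both
thresholds configurable; the strict inequalities are deliberate and
tested at the boundary).

## Co-occurrence network

Edges are Spearman rank correlations between taxa across samples (Pearson
available behind a flag).  Two-sided p-values use the t-distribution
approximation for n ≥ 10 samples and exact enumeration of all n!
pairings below that.  BH adjustment runs once over all tested pairs of
the merged table.  An edge requires |ρ| ≥ 0.8 (inclusive) **and**
adjusted p ≤ 0.01 (inclusive).  Taxa whose abundance vector is exactly
constant cannot be ranked and are excluded from testing (kept in the node
set, flagged); constancy is detected by exact equality, because floating
`std` of a constant vector can be a nonzero rounding residue.

Module detection runs greedy modularity agglomeration, Louvain, and fast
label propagation on the unweighted, sign-agnostic skeleton (negative
edges count as connections; a |ρ|-weighted mode exists).  Each partition
is scored by Newman–Girvan modularity Q and the best is kept, ties broken
in the fixed order greedy → Louvain → label propagation; Louvain and
label propagation are seeded, so results are reproducible.  Module IDs
are relabeled 0, 1, 2, … by decreasing size.  An edgeless network gets
singleton modules with Q = 0.

## Node roles and keystone taxa

Within-module connectivity Z_i is the z-score of a node's within-module
degree against its module's within-degree distribution, with the
*population* standard deviation; modules of size 1 or with zero variance
give Z_i = 0 rather than NaN so that every node is classifiable.
Among-module connectivity is the participation coefficient
P_i = 1 − Σ_s (k_is / k_i)², with P_i = 0 for isolated nodes.  Role
thresholds are Z ≥ 2.5 and P ≥ 0.62, both inclusive.  Keystone taxa are
the union of network hubs, module hubs, and connectors.  A geometric
fact worth keeping in mind: a node whose links split over only two
modules has P ≤ 0.5, so connectors require contact with at least three
modules.

## Robustness (removal simulation)

For each removal fraction f (default grid 0.005 to 1.0 in steps of
0.005) and each of 200 replicates, ⌊fN + 0.5⌋ nodes are removed
uniformly at random, then any node left with zero remaining edges is
deleted, iterated to a fixed point (secondary extinction).  Nodes that
were isolated in the original network are exempt — they cannot lose
links — unless explicitly included.  An abundance-weighted variant
requires retained interaction strength > 0 instead of retained degree;
with strictly positive |ρ| weights the two coincide.  A targeted mode
removes the highest-degree nodes deterministically.  Curve comparison
uses per-fraction mean differences with a bootstrap percentile CI over
replicates.

## Module–metabolite coupling

For each module m and sample j, SDI_mj is the Shannon index (nats) of
the module members' abundances *renormalized within the module* —
Shannon on the raw sub-vector would conflate the module's total
abundance with its internal evenness — and RA_mj is the summed relative
abundance with a per-module z-score across samples.  Each metabolite is
regressed on either predictor by ordinary least squares, one fit per
(module, metabolite) pair, with two-sided slope p-values and BH control
across all pairs.  Constant predictors are skipped with a warning.
"Higher alcohols" is available as a class sum (isoamyl alcohol +
phenethyl alcohol + isobutanol) via the alias mechanism when those
columns exist.

## Sloan neutral model

With community size N (rounded mean sample depth), detection limit
d = 1/N, and metacommunity relative abundance p (estimated by the mean
relative abundance across samples), the neutral expectation for a
taxon's occurrence frequency is

    f_pred(p; m) = 1 − BetaCDF(d; N·m·p, N·m·(1−p)),

the tail of the stationary Beta distribution of local relative
abundance under drift plus immigration at rate m.  m is estimated by
bounded scalar least squares of observed frequencies on f_pred
(m ∈ (10⁻⁶, 1]); R² = 1 − SSR/SST.  Taxa absent from every sample are
excluded.  A binomial-likelihood fit is intentionally not the default:
the least-squares frequency-scale fit is the convention of the cited
implementation lineage.

**Partition band.** A taxon is "neutral" when its observed frequency lies
inside the 95 % band around f_pred.  The default band is the Wilson
binomial confidence interval of f_pred at S samples, which models the
sampling noise of a frequency estimated from S samples (sd ≈ 0.1 at
S = 24) — this is what makes ~80 % of genuinely neutral taxa fall inside
the band.  A taxon-bootstrap percentile band (resampling taxa,
refitting m, taking 2.5/97.5 percentiles of the predicted curve) is
available via `ci_method="bootstrap"`; it reflects only the uncertainty
in m, is far narrower, and partitions most taxa non-neutral — useful for
visualizing fit uncertainty, not for the neutral/non-neutral partition.
The taxon bootstrap always provides the CI for m.

**Known bias.** Fitting against p̂ (estimated from the same samples) and
conditioning on taxa observed at least once biases m̂ upward; at the
reference conditions (500 taxa, 24 samples, N = 10⁴, m = 0.1) the median
fitted m is ≈ 0.125.  The acceptance suite checks recovery within
[0.07, 0.13] at those conditions and within a factor of two for
m ∈ {0.01, 0.1, 0.5}.

The forward simulator draws each sample's composition from
Dirichlet(N·m·meta_p) — whose marginals are exactly the Beta
distributions above — followed by a multinomial of depth N.

## Normalized stochasticity ratio (NST)

For every within-group sample pair, the observed dissimilarity D_ij
(Bray–Curtis, or Jaccard; the abundance-weighted Jaccard is the Ružička
form 1 − Σmin/Σmax) is compared to its mean E_ij over `n_rand`
(default 1000) draws from a proportional-proportional null model: each
sample keeps its richness and total count; which taxa occur is drawn
without replacement with probability proportional to the taxon's
observed occurrence frequency (Gumbel top-k); each occurring taxon gets
one individual and the rest of the depth is multinomial with probability
proportional to mean relative abundance.  Samples are the randomization
unit; the seed fixes the whole ensemble.

Per-pair stochasticity ratio (for ST): (1−E)/(1−D) when D < E, E/D when
D > E, 1 at equality — the closeness of observed to null, capped at 1.
For NST the per-pair *selection strength* is scaled against the
available range: SS = (D−E)/(1−E) for divergence, (E−D)/E for
convergence; NST = 1 − mean(SS), clamped to [0, 1] and reported as a
percentage.  Data generated by the null model itself then read near
100 %, perfectly deterministic data near 0 %, and 50 % is the
deterministic/stochastic boundary.  Published NST variants differ in
this normalization; the formula above is this package's documented
choice, and NST values are always null-model dependent — compare NSTs
only under the same null.

Because each pair contributes |D−E| of a *single* observed draw against
the null mean, NST approaches 100 % on null data only when pairwise
dissimilarities concentrate; in very small or extremely
dominance-skewed communities the irreducible per-pair fluctuation
deflates NST even without selection.  The benchmark fixtures therefore
use moderately rich communities (300 taxa, lognormal σ = 1, depth 10⁴,
12 samples); at those sizes null data measure ≈ 92 % and two-cluster
deterministic data ≈ 30 %.

## Indicator metabolites (random forest)

A random-forest classifier discriminates sample groups from metabolite
concentrations.  Reported importance is permutation-based mean decrease
in accuracy.  The cross-validation curve is rfcv-style: over a halving
feature grid (all, half, …, 1), features are re-ranked *within each
training fold* (by the fold forest's impurity importance — re-ranking
inside folds avoids selection bias) and the 10-fold CV error of the
top-k model is recorded; folds are stratified.  The selected panel size
is the smallest k whose mean CV error is within one standard error (of
the CV mean at the minimizing k) of the curve minimum — the canonical
1-SE rule, with a tolerance multiplier exposed.  Features are processed
in sorted-name order internally so results are invariant to input column
order (tree tie-breaking otherwise depends on it).

Limitations worth knowing: permutation importance masks exactly
collinear feature pairs (permuting one copy leaves the other intact), and
at n ≈ 72 samples the 10-fold CV curve cannot reliably distinguish a
4-feature panel from an 8-feature one — the curve's sampling noise is
comparable to the true error difference — so the selected k wanders
between adjacent grid points in a noticeable minority of replicates even
when the top-4 ranking is perfect.

## Calibration conventions

All permutation p-values use the add-one convention
p = (1 + #{stat_perm ≥ stat_obs}) / (1 + n_perm); exhaustive enumeration
over all n! orderings is available for small n and is what the oracle
tests compare against.  PERMANOVA partitions the Gower-centered distance
matrix sequentially (Type I, in the given factor order; a marginal mode
exists) with unrestricted permutations; sequential R² values plus the
residual sum to 1.  PCoA reports negative eigenvalues uncorrected.
Wilcoxon rank-sum is the default two-group per-taxon test on relative
abundances (t-test behind a flag); fold changes use a pseudo-count of
half the smallest nonzero relative abundance.  Under null simulations
(200 datasets) both PERMANOVA (199 permutations) and the per-taxon test
hold type-I error near 0.05.

## Synthetic-data generator

The generator emulates a two-workshop fermentation survey: 2 groups ×
6 sampling days (0, 2, 5, 10, 15, 30) × 4 replicates = 48 samples;
500 bacterial and 100 fungal taxa at depths 40 000 and 43 000 reads per
sample; metacommunity abundances lognormal with σ_log = 2.

Planted structure, all recorded in a `SyntheticTruth` object:

- **Neutral background** — all unplanted taxa follow the Sloan
  Dirichlet-multinomial draw at `m_true` (default 0.1).
- **Selected taxa** (5 %) — expected abundance multiplied by
  exp(slope · z(temperature)) with per-taxon slopes ≈ ±1.2; the
  temperature covariate rises over fermentation days with a group
  offset.  Idiosyncratic log-noise of 0.8 keeps selected taxa from
  forming a spurious ultra-dense correlation cluster of their own
  (which would also tip the modularity balance of the planted blocks —
  see below).
- **Modules** — 5 blocks of 12 bacterial taxa sharing a per-module latent
  factor (σ = 1, member log-noise 0.15), pinned at moderate metacommunity
  abundance (mean RA 4·10⁻³) so counting noise does not erode the planted
  correlations.  Factors are built from orthonormalized basis vectors, so
  their *sample* correlations equal their targets exactly instead of
  fluctuating by ~n^(-1/2).
- **Connectors** — 3 taxa riding a connector axis x with loading
  c = 0.92 onto the first three module factors, whose residuals form a
  regular simplex around x (the geometric minimum of their mutual
  correlation, 1.5c² − 0.5 ≈ 0.77).  This is forced by two constraints:
  a variable's squared correlations with orthogonal factors sum to at
  most 1, so a connector correlating ≥ 0.8 with three blocks requires
  correlated blocks; and P_i ≥ 0.62 requires spanning ≥ 3 modules.  The
  resulting connector–member correlations (≈ 0.86 after noise) sit above
  the 0.8 edge threshold while between-block member correlations
  (≈ 0.63) sit below it.  Module, connector, and selected taxa bypass
  the neutral Dirichlet layer (they are non-neutral by construction);
  only multinomial counting noise applies on top of their planted signal.
- **Metabolites** — ethyl acetate = 8 − 1.5·SDI(module 0) + noise and
  higher alcohols = 2 + 2.0·SDI(module 0) + noise, with noise calibrated
  to a target correlation of 0.7; four group-indicator metabolites with
  per-feature shift 1.5 within-sd (≈ 3σ combined over the panel); and
  24 noise metabolites that co-vary in classes through 3 latent sample
  factors, as real flavor panels do.

Identical seeds give identical datasets (all draws derive from one
`SeedSequence`).

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: sequencing error and chimeras,
compositional bias between libraries, taxon-specific amplification,
temporal autocorrelation beyond the smooth temperature trend, phylogenetic
structure (no tree exists anywhere in this pipeline), and interaction
*mechanisms* — the planted "modules" are statistical co-variation, not
mechanistic cross-feeding.  Rank-based edge detection also adds ~0.03–0.05
of block-level Spearman jitter on top of the exact factor geometry at
48 samples, so planted-structure recovery is near-perfect but not
guaranteed at every seed; the benchmark seeds are fixed and documented.

## Problem sizes

Benchmarks run at: neutral recovery, 20 datasets × (500 taxa,
24 samples, depth 10⁴); NST, 20 paired datasets × (300 taxa, 12 samples,
1000 null draws); network recovery, the default 48-sample survey;
slope recovery, 100 datasets; indicator recovery, 25 datasets ×
(72 samples, 34 metabolites, 100 trees); calibration, 200 null
simulations per test.  These sizes were chosen to make each recovery
property measurable with comfortable statistical margin on a single CPU.
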