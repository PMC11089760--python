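# Methods

## Model and assumptions

All predictors share one assumption: lncRNAs with similar miRNA interaction
profiles tend to be involved in similar diseases, and the involvement is
mediated by those miRNAs. The data model is a tripartite graph with vertex
classes `L` (lncRNAs), `M` (miRNAs), `D` (diseases) and edges only between
adjacent classes: validated lncRNA–miRNA interactions `I` and known
miRNA–disease associations `A`. Identifiers are opaque, case-sensitive
database symbols; the three classes are disjoint namespaces and no
cross-database harmonisation is attempted. Verified lncRNA–disease pairs
never enter prediction, which keeps gold standards independent at
evaluation time — the price is that every non-gold pair must be treated as
a negative even though some are merely unverified, a standard caveat that
biases absolute AUC/AUPR downward without affecting method comparisons.

### Neighborhood score (NGH)

For a pair `(l, d)` the score is a convex combination of two
intersection-over-union terms: the direct overlap of `M_l` and `M_d`, and
the overlap contributed by the *neighbors* of `l` (lncRNAs sharing at least
one miRNA with it), where the neighbor term unions the per-neighbor
intersections and unions. A vertex is not its own neighbor; including it
would count the direct evidence twice. Both ratios lie in `[0, 1]`, so the
score does too. A ratio whose denominator is empty contributes 0: no
evidence, no score. Note an asymmetry that matters in dense graphs: every
neighbor enlarges the neighbor-term denominator through its full profile,
but only its shared miRNAs enlarge the numerator — promiscuous, weakly
relevant neighbors therefore dilute the score.

The balance parameter `alpha` defaults to 0.5 (equal weight; unitless).
`alpha=1` reduces to profile Jaccard similarity, `alpha=0` to a purely
neighborhood-driven score; the test suite exercises the full sweep
{0, 0.25, 0.5, 0.75, 1}. Normalisation divides all scores by their grand
total; it changes no ordering and exists so the score table can serve as a
probability-like relationship matrix for the collaborative-filtering
booster.

### Collaborative filtering (CF and NGH-CF)

The relationship matrix `R` (lncRNAs × diseases) is filled binarily (CF:
1 iff the pair shares a miRNA) or with normalised neighborhood scores
(NGH-CF). Alternating least squares factorises `R` over its nonzero index
set `chi` only — zeros are unobserved, not negatives — with an L2 penalty
on both factor blocks. Each half-step solves the exact ridge normal
equations per row/column, so the penalised objective is non-increasing
across alternations by construction (asserted in tests). Rows or columns
with no observed entries get the zero vector, the ridge minimiser.

Parameters, defaults, and rationale:

* `f` (latent dimension, default 10): must be well below `min(|L|, |D|)`
  for imputation to occur — at full rank the factorisation reproduces `R`
  and adds nothing. The default targets realistically sized inputs
  (hundreds to thousands per side). Benchmark-scale analyses in this
  package use `f = 3` on the 15×10 synthetic matrix, matching the number
  of planted association regimes; `f = 10` is full-rank there and provably
  cannot reorder anything.
* `reg` (ridge weight λ, default 0.1, unitless): deliberately firm. With a
  weak penalty (we measured λ = 0.01) and moderate `f`, ALS memorises the
  observed entries and the out-of-sample inner products — the predictions
  the method exists for — degenerate to noise: on an implanted-block graph,
  planted-pair recovery in the top decile fell from 1.0 (λ ≥ 0.05) to 0.0
  (λ = 0.01, f ≥ 10), and the top decile became unstable across `f`. With
  λ = 0.1 both recovery and cross-`f` stability are restored. λ = 0 is
  supported but falls back to least-squares solves and can legitimately
  produce rank-deficient systems; a non-finite objective raises with advice
  to use λ > 0.
* `max_iter` 50 / `tol` 1e-4: the stopping rule is relative decrease of the
  objective per full alternation; the benchmark problems converge in well
  under 50 iterations.
* `seed` (default 42): disease factors initialise from seeded standard
  normals scaled by `1/√f`; lncRNA factors are solved first. Same seed,
  same factors, bit for bit.
* `rescale` (NGH-CF only, default on): normalised scores sum to 1 over all
  `h·k` entries, so their magnitude shrinks with matrix size; dividing `R`
  by its maximum gives λ a size-independent meaning. A positive scaling
  cannot change the input ordering.

### Hypergeometric baseline (HGLDA-style)

Each pair's profile overlap is tested against the hypergeometric null:
drawing `|M_d|` of the graph's `|M|` miRNAs, the probability of an overlap
at least as large as observed. Taking the whole miRNA universe of the graph
as the population is this package's convention. P-values are BH-corrected
across all pairs and ranked ascending. Ties are resolved by the raw
p-value, then lexicographically: zero-overlap pairs have raw tail
probability exactly 1 and therefore always occupy the bottom tie-group,
below every pair with any overlap evidence. This ordering is what makes the
baseline structurally blind to neighborhood-only associations.

## Evaluation conventions

* **ROC/AUC** via threshold sweep with tied scores collapsed into single
  steps; trapezoidal area. Tests cross-check against the tie-corrected
  Mann–Whitney statistic.
* **PR/AUPR**: the curve is sampled where recall increases, the precision
  envelope (running maximum from high recall downwards) is interpolated,
  and the area is the trapezoid over recall anchored at
  `(0, first envelope precision)`. Under this construction AUPR is never
  below the positive prevalence, for any labeling — the raw per-threshold
  trapezoid does not have that property.
* **F1 sweep**: thresholds are the 0.05-step grid on (0, 1) plus every
  distinct score, so the optimum cannot fall between grid points; reported
  is the maximum F1 and the *smallest* threshold attaining it. F1 is 0 when
  precision + recall is 0.
* **Top-fraction operations** (rank agreement, set recovery) take the best
  `ceil(fraction · n)` pairs; set-recovery rows are non-decreasing in the
  fraction by construction.

## Edge-deletion robustness

The protocol deletes a uniform random fraction (5–20 %) of LMI edges, MDA
edges, or both (half and half), refits the chosen method, and averages AUC
against a fixed gold standard over repeated runs (default 20). Edge counts
use floor rounding; in `both` mode each side loses `floor(fraction/2 · n)`
edges. Vertices are never removed, so the ranked universe is constant.
Repeat `r` perturbs with seed `base_seed + r`; one perturbed graph per
repeat is shared by whatever method is being measured. A repeat whose
labeled rank degenerates to a single class is excluded from the mean with a
warning.

## Synthetic benchmark

### What it emulates

A 15 lncRNA × 35 miRNA × 10 disease universe in which 54 planted
associations fall into three regimes — strong direct overlap (set 1, 26
pairs, 3–4 shared miRNAs), minimal direct overlap with a strong
neighborhood (set 2, 16 pairs, 1 shared miRNA, 2–5 strongly linked
neighbors), and neighborhood only (set 3, 12 pairs, 0 shared miRNAs) — plus
23 weakly linked "other" pairs. The benchmark ships as a *constraint table*
(per pair: shared-miRNA count, count of neighbors sharing with the disease,
size of the union of their shares), because counts, not edge identities,
are what define the regimes; a seeded constructor realises a concrete edge
list.

### Construction and its limits

The constructor allocates shared miRNAs greedily (each candidate move is
scored by the incidental structure it would create: new neighbor links, new
incidental pair overlaps, union dilution), wires neighborhoods, and then
runs a seeded simulated-annealing repair over single edge toggles that
never disturbs a constrained shared count. Direct-overlap counts of sets
1–3 are **hard**: the build fails rather than miss one, and set-3 pairs are
guaranteed zero overlap. Neighborhood counts are **soft**: they are
mutually coupled (every neighbor edge perturbs other rows' counts) and the
table is not exactly realisable within the 35-miRNA budget — e.g. one row
demands a neighbor union of 15 miRNAs from 3 neighbors whose own listed
direct counts cap their joint contribution at 9, which forces unlisted
"donor" pairs with substantial overlap to exist. Four table rows duplicate
pairs of the main sets with contradictory counts and are excluded as
conflicts. Every residual mismatch is enumerated per row in the
`SatisfactionReport`; nothing is silently dropped. The default seed is the
deviation minimiser found by a packaging-time search.

Because graph realisations differ across seeds and the regime boundaries
are tight (one rank position can move a 1/12 recovery step), benchmark
method comparisons in the test suite are averaged over five constructor
seeds with the ALS seed fixed.

### What passing does and does not show

The benchmark shows that the implementations behave as designed in a
controlled topology: the hypergeometric baseline can never rank a
zero-overlap pair above any overlap evidence, the neighborhood score gives
set-3 pairs nonzero signal, and low-rank factorisation recovers some
neighborhood-only pairs that the raw score leaves behind. It does *not*
calibrate absolute performance on real data: real LMI/MDA networks are
orders of magnitude larger and sparser, their profile sizes are heavily
skewed, miRNA pools are not budget-limited, and annotation noise is not
modelled. Absolute AUCs on the benchmark are depressed by the donor pairs
the construction requires (they are counted as negatives) and should not be
read as estimates of real-data accuracy.

## Numerical choices and degenerate inputs

* Ranking ties break lexicographically by (lncRNA, disease) everywhere, so
  every rank is deterministic and reproducible.
* An all-zero score table normalises to itself with a logged warning;
  factorising it is refused (empty `chi`).
* `f > min(h, k)` warns (over-parameterised) but proceeds.
* Scores are written with 6 significant digits; robustness grids with 2
  decimals.
* Seeds: one `numpy` Generator per seeded operation; derived seeds are
  plain integer offsets; nothing reads global random state.

## Known limitations

* The neighborhood is one hop; multi-hop propagation and weighted edges are
  out of scope.
* The hypergeometric baseline's population convention (all miRNAs of the
  graph) is one defensible choice among several; it is used only for
  comparison.
* The benchmark constructor satisfies neighborhood counts approximately
  (see above); consumers needing exact neighborhood topology should treat
  the constraint table, not any one realisation, as ground truth.
* With no verified negatives, precision-type metrics undercount true
  performance on real data by design.
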