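# Methods

This note records the models behind each analysis chain, the defaults and
why they were chosen, the numerical conventions, and what the synthetic
generators do and do not emulate.

## Bone color coding

**Model.** The contact matrix is an undirected graph G = (V, E) over named
structures; a labeling is a bijection f: V → {1..n}. The quality of a
labeling is its antibandwidth AB(f) = min over edges of |f(u) − f(v)|,
defined as n for an edgeless graph so the score is always a positive
integer (no edge ever constrains the palette). Maximizing AB is NP-hard, so
the production path is heuristic and an exact solver exists only as a
reference.

**Greedy construction.** Structures and free labels are paired one at a
time; the pair maximizing the minimum label distance to already-placed
contact neighbors wins, with ties broken by higher degree (constrained
structures placed early), then lexicographically smaller name, then smaller
label. Name-based tie-breaking is applied after canonically sorting the
structures, so permuting input rows cannot change the result.

**Local search.** Label-pair swaps are accepted while the *sorted vector of
edge label distances* strictly increases lexicographically. Comparing the
whole vector rather than only its minimum matters: it first raises the
antibandwidth whenever a swap can, and on plateaus it reduces the number of
edges sitting at the minimum, which unlocks later raising swaps. On paths
and complete graphs up to n = 10 this reaches the exact optimum found by
branch-and-bound; on random proximity graphs it occasionally stops one step
short, which is acceptable — sub-optimal palettes are still usable, only
less contrasting. Strict lexicographic ascent guarantees termination.

**Exact solver.** Branch-and-bound over label assignments in increasing
label order; since the partial minimum distance only decreases as labels
are added, any branch whose running minimum cannot beat the incumbent is
cut. Refused above n = 10 (factorial blow-up).

**Colors.** Label k maps to ramp position (k−1)/(n−1) (position 0 for a
single structure); no gamma correction. Two ramps are built in: an HSV hue
sweep 0°→300° at full saturation/value (the 300° endpoint avoids wrapping
back into red) and a gray ramp. The default color metric is Euclidean
distance on 0–255 RGB channels; a CIELAB mode is available because
perceptual uniformity is the natural refinement, but RGB remains the
default for transparency and reproducibility. Unknown ('?') contacts
default to *absent* — an unverified contact should not constrain the
palette — with a `present` override for conservative palettes.

## Body size and encephalization

**RMA regression.** For allometric data both variables carry measurement
error, so ordinary least squares is inappropriate; the reduced major axis
slope is b = sign(r)·s_y/s_x with intercept ȳ − b·x̄ on the transformed
scale, and r² is the squared Pearson correlation. Both `log10` (default,
standard for allometric scaling) and `linear` modes exist. Degenerate
inputs (n < 3, zero variance, nonpositive values under log10) are rejected
rather than silently fitted.

**Mass equations.** The limb-length → body-mass regressions are
configuration data, not code: each is log-linear,
log₁₀(M/g) = a + Σ bᵢ·log₁₀(Lᵢ/mm), loaded from JSON. One humerus value and
several femur predictions expand combinatorially (univariate humerus,
univariate femur per femur value, multivariate humerus+femur per pair), so
1 humerus + 3 femurs yields 7 estimates, summarized by min/max/mean. The
*packaged* coefficients file is an explicitly labelled synthetic stand-in
(`mass_equations_synthetic.json`): its slopes sit in the 2.5–2.8 range
typical of stylopodial length–mass scaling and its intercepts put a small
dicynodont in the hundreds-of-grams regime, but real analyses must supply
the published coefficients.

**Encephalization.** Brain mass E (g) = endocast volume (mm³) × density
(g/cm³) / 1000, density defaulting to 1.0 g/cm³ (the standard brain-tissue
assumption). EQ = E / (0.055 · P^0.74) with body mass P in grams
(Eisenberg's mammalian scaling). Full precision is kept internally; a
2-decimal convenience rounding is exposed for reporting. Note that with a
1062 mm³ endocast and P = 491 g the quotient is 0.19695, i.e. 0.20 when
rounded half-up but 0.19 when truncated — published values at two decimals
can differ by one last-place unit from recomputation with rounded inputs.
Brain-part fractions are 100·Σparts/total, reported at one decimal; a part
sum exceeding the total warns but still computes (overlapping part
definitions are common).

## Parsimony on mixed matrices

**Scoring.** Unordered discrete characters use Fitch optimization: a
post-order pass over the tree rooted on the edge of the first taxon, each
internal node taking the intersection of its children's state sets, or
their union at cost 1 when disjoint. Missing and inapplicable cells ('?')
both carry the column's full observed alphabet and can never add length.
Continuous characters are additive and use Farris interval optimization:
each internal node takes the intersection of child intervals, or, when
disjoint, adds the gap to the length and takes the between-interval
closure [min(hi), max(lo)]. Missing continuous cells are unbounded
intervals. State sets are encoded as bitmasks and intervals as arrays, so
all columns of a partition are scored in one vectorized pass; a 174 × 40
matrix scores in milliseconds. Continuous values are used exactly as
printed — no internal rescaling — with per-column weights available if a
reference program's convention must be matched.

**Floors and ceilings.** Per character, the minimum length over any tree is
(number of necessary states − 1) for discrete columns (computed as a
minimal hitting set so polymorphic cells are not overcounted) and
max(lo) − min(hi) for continuous columns; the maximum is the star-tree
length (non-modal cell count, resp. the median-center L1 cost). These give
CI = Σmin/L (defined as 1 when L = 0) and RI = (Σmax − L)/(Σmax − Σmin),
reported as undefined when Σmax = Σmin. All sums apply column weights, so
doubling every weight doubles L but leaves CI and RI unchanged.

**Search.** Desk-scale only, by design: each start draws a random taxon
addition sequence (seeded), places taxa greedily on the best edge, then
steepest-descent SPR swapping until no neighbor improves; all distinct
best trees across starts are returned. Correctness is defined against
brute-force enumeration on small instances (105 topologies at 6 taxa), not
against large-matrix heuristics (sectorial search, ratchet, drifting and
tree fusing are out of scope). Trees are handled unrooted throughout; a
display root (an outgroup such as the most basal taxon) affects only
Newick output.

**Supports.** Symmetric resampling perturbs each character independently
with probability p (default 0.33, the conventional strength, always echoed
in the output table): up-weight ×2 or down-weight ×0 with equal chance, so
the expected weight is unchanged. Each replicate re-runs the search on
perturbed weights and a reference clade counts as recovered when it is in
the strict consensus of the replicate's best trees. Bremer decay is
estimated from a seeded pool of suboptimal trees: every topology evaluated
during repeated hill climbs whose length is within `max_extra_steps` of the
best length is retained (duplicates removed), and a clade's decay is the
minimum extra length among pool trees lacking it, reported as
"> max_extra_steps" when none does. On 5-taxon instances the pool covers
all 15 topologies and the decay values match exhaustive scoring exactly.
All stochastic operations take explicit seeds; there is no hidden global
RNG state.

**TNT dialect.** The parser accepts `xread` with `nchar ntax` dimensions,
an optional `&[continuous]` block (values `1.230` or ranges `0.500-0.700`),
discrete blocks with symbols 0–9, '?'/'-' missing and `[01]` polymorphisms,
and `ccode /w` weight statements; ordering flags are ignored because the
scoring conventions (discrete unordered, continuous additive) are fixed.
Errors carry line numbers. The writer emits continuous values at 3 decimals,
the usual precision of published continuous codings, and the
write→parse round trip is exact.

## Synthetic data

The generators define the study conditions for all tests:

* **Contact graphs** — n points uniform in the unit square, edges under a
  proximity radius (default 0.35 at n = 20), nearest-pair augmentation
  until connected. Emulates the sparsity and clustering of a skull contact
  matrix, not actual cranial topology. A hand-built 27-bone skull matrix
  with plausible dicynodont contacts and five '?' cells ships as
  `data/skull_contacts_synthetic.csv` for fixture-style tests.
* **Allometric tables** — skull lengths uniform on 40–400 mm, limb length
  from a known log-linear law plus Gaussian noise on the log scale. The
  presets emulate the compiled anomodont datasets: 46 specimens
  (skull–humerus) and 26 (skull–femur), generating lines placing a 63 mm
  skull at ≈17 mm humerus and ≈47 mm femur, and noise set *analytically*
  (σ² = b²·var(log₁₀X)·(1−r²)/r²) so the expected r² equals the published
  0.924 and 0.903. What passing tests show is that the pipeline recovers
  known generating parameters at realistic noise — not that it reproduces
  any particular empirical table.
* **Character matrices** — discrete characters under a symmetric k-state
  Markov model (P(stay) = 1/k + (1−1/k)·e^(−k·rate·t/(k−1))), continuous
  characters by Brownian motion from a root value of 0, on a supplied tree
  or a random topology with exponential branch lengths. All transitions are
  equally likely because the scored characters are unordered and equally
  weighted. Invariant columns are kept by default (no ascertainment
  filtering), with an opt-in resampling toggle. Real morphological
  matrices violate these assumptions freely (correlated characters,
  asymmetric rates, missing-data structure); the simulations establish
  algorithmic correctness, not realism.

## Problem sizes used in the routine checks

The bundled end-to-end checks run at sizes chosen to keep the full suite in
seconds while still exercising every code path: 174-character × 40-taxon
matrices for parse/score timing, 6-taxon × ~45-character matrices for
search-vs-enumeration (20 seeds), 5-taxon matrices for decay-vs-exhaustive,
100 random graphs of n ≤ 8 for labeling-vs-exact, and 200 replicates for
RMA recovery rates. The full-scale support experiment of a real study
(tens of thousands of resampling replicates, hundreds of thousands of
suboptimal trees) is the same code run longer, but is not part of the test
suite.

## Known limitations

* The antibandwidth heuristic has no approximation guarantee; only paths
  and cliques are verified optimal classes.
* Bremer decay from hill-climb pools is a lower-bound-style estimate on
  larger matrices, exact only when the pool saturates the near-optimal set.
* The femur-side mass chain (skull→femur proxy and femur equations) uses
  the same machinery as the humerus side but its packaged coefficients are
  synthetic placeholders.
* TNT `ccode` parsing covers weights only; exotic per-character commands
  are ignored.
* No phylogenetically corrected regression and no implied weighting, by
  scope.
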