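# Methods

This note documents the models, algorithms and numerical conventions behind
`glomnet`, the design choices made where the design was genuinely open, and
what the synthetic validation does and does not establish.

## Data model and pre-processing

Input is a rectangular units × variables real matrix (rows: observational
units such as counties; columns: indicator variables), with missing entries
allowed and one optional column flagged as the outcome.  At least 3 units
are required — the minimum for a meaningful correlation.

Two conventions are fixed once and used everywhere:

* **Sample SD (n − 1 denominator)** for both the low-variance filter and
  z-scoring.  The filter drops variables whose SD over non-missing entries
  is ≤ ε (default ε = 1e-8, i.e. essentially constant columns); the outcome
  is always retained, with a warning if it fails the cut.  Filtering runs on
  the raw scale and precedes normalization — normalizing a near-constant
  column would amplify noise before the filter could see it.
* **Missing-value tokens** in delimited files: empty string, `NA`, `NaN`
  (case-insensitive), covering the common CSV dialects.

Normalization is per-variable z-scoring (mean 0, SD 1 over non-missing
entries).  Pearson correlation is affine-invariant, so this choice cannot
change the correlation graph; it matters only for any downstream use of the
preprocessed matrix itself.  Rank-based analysis is available by choosing
Spearman correlation, which is computed as Pearson on average ranks
(standard tie handling).

## Correlation graph

Correlations are pairwise-complete: each pair (i, j) uses exactly the units
observed for both variables.  Pairs with fewer than `min_overlap` complete
observations (default 10) are marked *missing*, as are pairs whose
pairwise-complete subset leaves either variable with zero variance; missing
entries never become edges.  The default of 10 reflects the practical floor
below which a correlation coefficient is too unstable to support an edge;
it is configurable.  On complete data the computation takes a BLAS-backed
fast path; with missing data it delegates to pandas' pairwise-complete
`corr`.

Thresholding at t keeps edge (i, j) iff |M(i, j)| ≥ t.  Absolute values are
the default because positive and negative relationships are of comparable
interest; a signed mode exists.  The `SimpleGraph` that results is strictly
unweighted; the correlation graph is retained alongside it because
polarity and anchoring computations downstream need the signed weights.

## Threshold selection

The toolkit profiles a grid of thresholds (default 0.30–0.95, step 0.01),
recording edge count, non-singleton component count, largest component
size, the largest adjacency eigenvalue λ₁, and (for small graphs, or on
request) maximum clique size.  λ₁ is monotonically non-increasing in t
(eigenvalue interlacing under edge deletion on a fixed vertex set), which
the profiler asserts; nested edge sets also mean that grid points with
equal edge counts carry identical graphs, so their statistics are reused
rather than recomputed.

Selection from the profile had to be made concrete.  As t rises, λ₁ passes
through up to three regimes: a *noise* regime dominated by abundant weak
edges, which collapses quickly; a *stable* regime where only densely
intercorrelated variable groups survive; and the eventual *dissolution* of
those groups themselves, ending in an empty graph.  A rule that simply
takes the largest relative drop in λ₁ conflates the last two regimes: the
final drops toward an empty graph are always the largest in relative terms
(the very last is 100%), so on clean data it selects a threshold that
destroys the structure it was meant to isolate.

The implemented rule therefore looks for *stability plateaus*: maximal runs
of consecutive grid points whose per-step relative drop in the statistic is
at most 3% while the statistic stays non-trivial (λ₁ ≥ 2, the level of a
single triangle; maximum clique ≥ 3).  The longest plateau is taken to be
the surviving dense structure, and its first grid point is the selected
threshold — the smallest t at which the noise regime has collapsed.  Ties
in plateau length break toward larger t (the sparser, more conservative
graph).  If the longest plateau spans the entire grid (a flat profile) or
no grid point qualifies, the smallest grid point is returned with an
explicit "no inflection found" warning; on data whose background
correlations all fall below the grid start this is exactly the right
answer, since every grid point then yields the same signal-only graph.
Both the spectral (λ₁) and the clique-size variant of the rule are offered;
runs record which criterion produced the selected t, and runner-up plateaus
are logged.

## Exact cliques via the vertex-cover dual

A maximum clique of G is the complement of a minimum vertex cover of the
complement graph Ḡ: |max_clique(G)| + |min_vc(Ḡ)| = |V|.  Vertex cover is
solved exactly by a bounded search tree over per-vertex bitsets
(Python integers), with:

* kernelization — degree-0 removal, degree-1 forced neighbour, and the
  high-degree rule (any vertex whose degree exceeds the remaining budget
  must be in the cover);
* a greedy max-degree cover as the initial upper bound;
* a greedy maximal-matching lower bound for pruning;
* branching on the highest-degree vertex (take it, or take its whole
  neighbourhood), ties broken by vertex index.

The clique search first decomposes the input into connected components — a
maximum clique lives inside one component, and the vertex-cover dual of a
small component's complement is vastly cheaper than that of the whole
graph's.  Components too small to beat the incumbent are skipped; among
equal-sized optima the lexicographically smaller member set (under the
fixed branching order) is returned, making results deterministic for a
fixed vertex order.  A configurable node budget aborts the search cleanly,
returning the best cover found so far (always valid, possibly not minimum)
with a `proven_optimal = False` flag rather than hanging on adversarial
inputs.

Maximal-clique enumeration (pivoting Bron–Kerbosch on the same bitsets,
guarded to 2000 vertices by default) and two deliberately naive exhaustive
searches are included as independent oracles for testing; the oracles share
no code path with the solver they check.

Crown/LP kernels and parallel execution are out of scope; the kernelization
hook is the natural extension point.

## Paracliques

A paraclique is grown from a maximum clique core C in a single pass: every
non-member adjacent to at least |C| − g core members is glommed in, with g
the glom factor.  Admission is evaluated against the original core, not the
growing member set — the canonical definition; a fixpoint variant that
re-evaluates against the grown set is available behind a flag and is not
the default, since it can chain outward indefinitely.  Iterated extraction
removes each paraclique's members (or only its core, when vertex overlap
between subgraphs is enabled) and recomputes the next maximum clique until
it falls below the core floor.  With overlap on, paracliques may share
glommed vertices but never core vertices.

Defaults g = 1 and min_core = 5: a small glom factor keeps glommed vertices
nearly fully connected to the core, and a core floor of 5 keeps extraction
at the "few tens of vertices" scale the method targets while stopping it
from enumerating noise triangles.  Both are configuration fields and are
recorded in run provenance.

Anchored extraction is the lighter-weight alternative for variables of
established importance that fail to reach clique-level correlations: the
anchor plus every variable correlated with it at |r| ≥ r_min, signed
correlations reported alongside.

## Outcome ranking and coarsening

Each paraclique is scored by the **median of |r(outcome, v)|** over its
members (missing correlations excluded; even counts take the mean of the
central pair).  Absolute values match the absolute-correlation
thresholding convention — a block of variables strongly *negatively*
correlated with the outcome is as interesting as a positive one; a signed
mode exists.  Paracliques with median ≥ cutoff (default 0.38) are marked
selected.  The outcome is excluded from graph construction, so it can never
sit inside a paraclique and rank itself.

Coarsening makes paracliques the nodes of a new graph.  For nodes P and Q,
all cross correlations r(u, v), u ∈ P, v ∈ Q, u ≠ v (glommed members
included — they are full members of the variable group) give:

* weight = median |r| over non-missing cross pairs;
* polarity = the strict-majority sign of the signed values; a tie falls
  back to the sign of the median signed value, and +1 if that is zero.
  "Majority sign" alone is not total, so the fallback chain makes the rule
  deterministic.

Node pairs with no usable cross correlation are left out and logged.  In
pipeline runs, coarsened nodes are labelled by their smallest core member —
a naming scheme that is stable across cohorts, so that two cohorts'
coarsened graphs can be compared vertex-by-vertex.

**Density matching** compares two coarsened graphs fairly: after optional
base thresholds (default none), the target density d\* is the smaller of
the two graphs' densities, and each graph retains its top
k = round(d\* · n(n−1)/2) edges by weight (ties at the cut broken by weight
descending, then lexicographic node pair).  Top-k retention is monotone,
deterministic and parameter-free; the matched densities agree within one
edge's worth of the smaller graph by construction.

## Differential comparison

`differential_summary` is purely structural and descriptive: shared and
cohort-specific vertices; shared and cohort-specific edges *over the shared
vertex set* (so availability differences are reported separately from
structural ones); per-vertex degree differences on shared vertices; edge
polarity flips (coarsened inputs only); and the two graphs' densities.  It
is antisymmetric by construction.  No significance testing is attached —
the comparison is a hypothesis-generation device, and attaching p-values
would require multiple-comparison machinery deliberately left out of scope.

## Synthetic data

The generator emulates the statistical structure of county-level indicator
data with a Gaussian latent factor model.  Per unit, factors
f ~ N(0, P) with P a factor correlation matrix; a variable in block b with
loading a is x = a·f_b + √(1 − a²)·e with unit noise e, so the expected
within-block correlation is a² and the cross-block correlation is
aᵢaⱼP_ij.  Background variables are pure noise.  The outcome is
y = Σ_b w_b f_b + N(0, sd²), giving the closed-form outcome–variable
correlation a·(P w)_b / √(wᵀPw + sd²).  Optional MCAR missingness and
heavy additive outliers exercise the noisy, mis-measured character of real
aggregate data.  Everything is reproducible from the seed, which is
recorded in the ground truth.

Default scale — 10 blocks × 15 variables at loading 0.9 plus 450 background
variables over 1500 units — mirrors the regime of a few hundred indicator
variables over a national set of mid-sized counties.  Two calibrated
validation scenarios are fixed by closed form, not by tuning:

* outcome recovery wires the outcome to 3 blocks with unit weights and
  noise SD 0.49, placing wired medians at 0.9/√(3 + 0.49²) ≈ 0.50 and
  unwired medians near 0 at n = 1500;
* factor-correlation recovery uses two blocks at loading 0.99 with
  ρ = 0.5 over 500 units, so that the observable cross-block correlation
  a²ρ ≈ 0.49 is attenuated by under 2% — the scenario measures whether
  coarsening recovers the *factor* correlation, so the attenuation is kept
  inside the measurement tolerance by design.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring counties, non-Gaussian marginals and skewed rates,
heteroscedastic measurement error, block overlap (a variable loading on two
factors), and systematically missing (non-MCAR) data.  Passing the
synthetic recovery suite therefore demonstrates correctness of the
machinery and recoverability under clean factor structure — not performance
guarantees on real county data, where threshold selection in particular
will face messier spectra.

## Validation problem sizes

The shipped checks run at: 200 random graphs (n ≤ 18) for clique exactness
and duality against exhaustive search; 100 random graphs for the paraclique
contract; 50 random correlation matrices for threshold monotonicity; 20
county-scale replicates (600 variables × 1500 units) for planted-block and
outcome-ranking recovery; 20 replicates of the two-block scenario for
coarsening; and 50 random pairs each for density matching and differential
consistency.  These sizes keep the whole validation under a minute on one
CPU while leaving the binomial pass thresholds (≥ 90% / ≥ 95% of
replicates) statistically meaningful.

## Known limitations

* The vertex-cover search is exact but exponential in the worst case;
  pathological dense components beyond a few hundred vertices need the node
  budget (which degrades gracefully to best-found-so-far).
* Plateau-based threshold selection assumes the grid reaches into the
  stable regime; a grid ending inside the noise regime selects its start
  and warns.
* Mutual-information and Euclidean-distance edge weights are rejected with
  a clear message rather than half-implemented; partial correlations,
  shrinkage and Gaussian graphical models are likewise out of scope.
* Coarsened-node matching across cohorts relies on the smallest-core-member
  label; cohorts whose paracliques split or merge the same variables will
  partially mismatch, which the differential summary then reports as
  cohort-specific vertices.
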