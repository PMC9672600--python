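# Methods

This note records the models and procedures implemented in `fairspots`, the
parameter defaults and why they were chosen, the numerical conventions, and
what the synthetic experiments do and do not establish.

## Measures

**Noteworthiness.** A candidate is a k-subset of the ranked hot-spot list;
its noteworthiness is the sum of its members' ranks. Lower is better, the
top-k candidate attains k(k+1)/2, and no candidate can do better, which
makes the top-k selection the anchor of the N axis.

**Fairness.** The population covered by a candidate is the *union* of its
hot spots' member sets — each individual counts once no matter how many
chosen hot spots contain them, since each person is subjected to the policy
action once. For every protected attribute, the covered population's
categorical distribution is compared with the whole dataset's by Wasserstein
distance, and fairness is the sum over attributes. Zero means statistical
parity on every attribute.

Two ground metrics are available for the categorical Wasserstein distance.
The default, `unit`, is the discrete 0/1 metric: appropriate for nominal
attributes (religion, ethnicity) where categories have no order, and equal
to total variation, ½·L1. The alternative, `index`, places the v levels at
integer positions 0…v−1 and is appropriate for ordinal attributes (banded
income, education years); it is computed by `scipy.stats.wasserstein_distance`.
The two coincide on binary attributes, so for two-level schemas the choice
is immaterial. There is no universally right choice for multi-level nominal
data; `unit` is the default because the motivating protected attributes are
nominal.

## Bernoulli spatial scan

The built-in detector is the classical circular case/control scan: windows
are circles centered at each data point with radii equal to distances to
every other point (boundary inclusive), truncated at
`max_population_fraction` (default 0.5) of the dataset. Each window is
scored by the Bernoulli log-likelihood-ratio statistic with a high-rate
indicator (windows whose internal rate does not exceed the outside rate
score 0), using the 0·log 0 = 0 convention. Windows are ranked by score;
ties break toward smaller windows and then lexical member-id order, so the
ranking is invariant to dataset row order. Monte-Carlo significance testing
is deliberately out of scope: downstream selection consumes hot spots by
rank, not by p-value.

Two secondary-window policies are provided. `overlap="free"` keeps every
distinct window, so the top-m may contain heavily overlapping, nearly
nested circles on the same cluster. `overlap="disjoint"` greedily skips any
window sharing a member with a better-ranked one — the conventional
no-geographical-overlap reporting rule of scan-statistic tools. The free
policy is the module default (the selection layer is defined for arbitrary
set relationships between hot spots); the disjoint policy is what the
synthetic experiments use, because a ranked list of near-duplicates makes
every union demographically identical and collapses the N–F plane to a
line — a degenerate instance of the selection problem, not an interesting
one.

Coordinates are planar Euclidean by default; `coordinate_system="latlon"`
switches the scan (only) to haversine great-circle distances.

## Diverse Pareto-efficient selection

Domination is coordinate-wise: p dominates q when p is no larger on both N
and F and the two points are not coordinate-identical; coordinate-identical
points never dominate each other and are all retained on the frontier. The
frontier is computed by a vectorized pairwise test (the O(n²) route whose
cost dominates the search's complexity budget) with an O(n log n)
sort-and-sweep alternative that is tested to produce the identical set.

Diverse selection orders the frontier from best-N to best-F and picks
`count` points at the end-points of equal segments. The default `index`
spacing partitions the frontier *sequence* into count−1 equal-length runs —
it needs no normalization and treats the frontier as the discrete object it
is. An `arclength` mode instead spaces stations uniformly along the
min-max-normalized geometric trace of the frontier and snaps each station to
the nearest frontier point. Both modes always return actual candidates
(never interpolations), always include the two extreme points, and return
the whole frontier when it has at most `count` points.

**Exact solver.** Enumerates all C(m, k) subsets, extracts the global
frontier, applies diverse selection with τ. A budget guard (default
2 × 10⁶ subsets) refuses instances where enumeration is infeasible,
reporting the count.

**Beam solver.** The search space is organized as a prefix tree over
strictly increasing rank tuples. Level l holds candidate prefixes of size l;
children extend a node only by ranks large enough that the prefix can still
grow to size k (without this bound, beams near the lexical tail dead-end and
level k could be empty). At each level the candidate set is scored, its
Pareto frontier extracted, and a diverse b-sized subset of the frontier is
expanded into the next level; at level k the surviving frontier is sampled
down to τ. When a level frontier has fewer than b points the whole frontier
is kept — it is not padded with dominated nodes, which would dilute the
Pareto-efficiency heuristic. The candidate set at any level is at most b·m,
and total nodes evaluated at most m + (k−1)·b·m; the implementation records
the actual count on every result and the test suite asserts the bound.

The search is fully deterministic: all orderings are resolved by (N, F,
lexical rank tuple), and both solvers return results sorted by N ascending.
`SearchConfig.seed` is reserved for future stochastic variants and does not
influence the current algorithm. Setting b ≥ τ is recommended (and warned
about otherwise): the final τ points are drawn from a frontier whose
richness the beam width controls.

## Evaluation metrics

All metrics are computed after min-max normalizing N and F over the full
candidate universe (all C(m, k) subsets), so distances are commensurable; a
constant axis maps to 0. **DC** is the mean Euclidean distance between
index-paired members of two equally long result lists, both sorted by N
ascending (frontier order is the only canonical pairing). **Coverage** is
the fraction of universe candidates *outside the result set* dominated by
at least one result member; evaluating the dominated share over the
non-result candidates makes the boundary identities exact — the entire
skyline covers 1.0, and a unique worst point covers 0.0 — where dividing by
the whole universe would leave the skyline's own members uncovered by the
identity-excluding domination relation. **MD** is the minimum pairwise
normalized distance within a result; it is deliberately brittle (one close
pair drags it down) and should be read alongside coverage.

`evaluate_run` builds the universe, runs the exact solver, and reports DC,
both coverages, both MDs and wall times. When the beam legitimately returns
fewer than τ candidates (its explored final frontier was undersized — a
warning, not an error), DC is computed against the exact selection at that
smaller count so the comparison stays defined; coverage and MD comparisons
always use the full-τ exact result. Above the enumeration budget a partial
report is returned with the universe-dependent metrics marked unavailable.

## Synthetic data

The generator emulates a human-development survey: individuals on the unit
square, a binary deprivation label, and two binary protected attributes
with dataset marginals 0.27/0.73 and 0.21/0.79. Defaults: 1000 individuals,
10 planted disc clusters of radius 0.045 each holding 5% of the population,
centers rejection-sampled at least 3 radii apart, background hotness rate
0.05.

Two defaults encode the structure the selection problem presumes. First,
in-cluster hotness rates grade linearly from 0.9 down to 0.4 across
clusters, so the scan's ranking of clusters tracks the cluster index and
rank is a meaningful currency. Second, the demographic skew is correlated
with that order: the hotter half of the clusters over-represents each
attribute's first level (marginal reweighted ×4, renormalized), the milder
half over-represents the last level (×3). The most noteworthy selections
therefore cover skewed populations, and fairness must be *bought* by
substituting lower-ranked, oppositely skewed hot spots — producing curved
Pareto frontiers (typically 6–20 points at m = 15, k = 4). A single shared
skew direction makes every union equally unfair, and opposite skews within
the top clusters make fairness free; both collapse the frontier to a point
or two and were rejected for that reason. Skews, rates, marginals and the
schema are all overridable per cluster.

What the generator does **not** emulate: real geography (district shapes,
population density gradients), survey weights, spatial autocorrelation of
the protected attributes outside the planted clusters, missing data, and
numeric protected attributes. Passing tests on this generator show the
selection machinery behaves correctly on landscapes with a genuine
noteworthiness–fairness trade-off; they do not certify detection quality or
fairness levels on any particular real dataset.

`generate_nf_cloud` draws abstract N–F points from a Gaussian copula with a
prescribed correlation (negative → strong trade-off, large frontier) for
exercising frontier and selection geometry in isolation.

## Experiment scales

The bundled experiments run at desk scale: reference settings m = 20,
k = 5, τ = b = 5 (universe 15 504), the multi-seed approximation study at
m = 15, k = 4, τ = b = 4 over 20 seeds, and cluster-recovery runs at 1000
points over 10 seeds. These sizes keep exact enumeration — the evaluation's
ground truth — cheap enough to recompute everywhere while leaving the
search a five-order-of-magnitude node-count advantage to demonstrate.

## Known limitations

- One fairness dimension: multiple protected attributes are summed into a
  single F; trade-offs *between* attributes are not exposed as separate
  axes.
- Rank-sum noteworthiness ignores score gaps between consecutive hot spots;
  detectors exposing calibrated scores would support a score-weighted N.
- The beam offers no approximation guarantee; b trades quality for time,
  and gains taper beyond b ≈ 2τ in our runs.
- The scan's circular windows and data-point-centered family are the
  classical choices; elongated or irregular hot spots are represented only
  as unions of circles.
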