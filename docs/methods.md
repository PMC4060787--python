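# Methods

## Problem setting

Protein–protein interaction (PPI) networks are sparse, fragmented and
heavy-tailed: a few hub proteins carry much of the connectivity, many
pairs of proteins are mutually unreachable, and a protein can belong to
several functional modules at once. Distance-based clustering is
awkward here — shortest paths are undefined across components and
reciprocal-weight distances diverge — and hard partitions cannot
express shared subunits. This package clusters such networks with
intuitionistic fuzzy memberships computed directly from interaction
weights, and searches for good cluster centers with an artificial bee
colony (ABC) metaheuristic.

## Intuitionistic membership model

Every (node, center) pair receives a triple (u, v, π) on the simplex
u + v + π = 1: membership, non-membership, and hesitation (residual
uncertainty). The ingredients:

* **Distance.** d(i, vⱼ) = 0 if i = vⱼ; 1 − w̄(i, vⱼ) if the pair
  interacts (w̄ is the max-normalised weight, so the strongest edge has
  distance 0); otherwise a finite cap `d_max` (default 2.0). The cap
  replaces shortest-path or reciprocal-weight distances, both of which
  misbehave on fragmented interactomes. Any `d_max` > 1 only needs to
  dominate every adjacent distance; 2.0 keeps e^{d²} ≈ 54.6, making
  non-neighbours' memberships (≈ 0.018) clearly below any neighbour's.
* **Hesitation.** Derived from the interaction weight rather than set a
  priori. Two conventions ship. `as_printed` (default): π = w̄ for
  interacting pairs, 0 for non-interacting pairs, 1 at the center
  itself. `complement`: π = 1 − w̄, 1, and 0 respectively, so that a
  strong interaction means a *confident* assignment.
* **Membership.** u = (1 − π) / (e^{d²} + 1), v = 1 − π − u. Both
  components stay in [0, 1] for any π and d, and u decreases in both
  distance and hesitation.

Measured on the planted benchmark below (seeds 0–9), the two hesitation
conventions differ sharply in recovery power: mean composite f-measure
0.915 for `as_printed` versus 1.000 for `complement`. The cause is the
`as_printed` interplay of π = w̄ with u ∝ (1 − π): a node tied to its
center by a near-maximal weight is mostly "hesitant" and its membership
drops toward zero, occasionally below the non-neighbour floor.
`as_printed` remains the default as the original convention; switch to
`complement` (`--hesitation complement`) when recovery quality matters
more than convention fidelity.

Because a center's own hesitation makes its self-membership
uninformative (0 in `as_printed` mode), cluster assignment places each
center in its own cluster unconditionally; every other node joins its
argmax-membership cluster (ties to the lowest cluster index). With
`overlap_margin` θ > 0 a node also joins every cluster within θ of its
maximum membership, producing overlapping modules.

**Row normalisation (off by default).** Optionally each node's
membership row is rescaled to sum to exactly 1 by replacing the +1 in
the denominator with a row-specific scale t, the root of
g(t) = Σⱼ (1 − π)/(e^{d²} + t) − 1. g is strictly decreasing on
(−minⱼ e^{d²}, ∞), diverges at the left edge and vanishes at +∞, so the
root is unique, and at the root every rescaled membership is positive.
The solver runs secant iteration from (0.5, 2.0) with a bisection
fallback on a geometrically grown bracket, to |g| ≤ 1e-10; rows that
are fully hesitant (every π = 1, only possible for a center row with
c = 1) are left unnormalised. Note the root is negative whenever the
unscaled row sums below 1 — the common case for sparsely connected
nodes. Non-membership is recomputed as 1 − π − u and clamped at 0, with
clamped rows counted in the debug log. Normalisation rescales a row by
a common factor, so argmax assignments are unchanged; it matters only
when membership values are exported and compared across nodes.

## Clustering criterion

A candidate clustering {I₁, …, I_c} is scored (lower is better) by

    fval = (1/c²) Σ_{i≠j} sim(I_i, I_j) + 1/DEW   (DEW ≠ 0; else the sim term alone)

with sim(I, J) = Σ_{x∈I, y∈J} c(x, y) / max(|I|, |J|), connection
strength c(x, y) = 1 for x = y, w̄(x, y) for interacting pairs, 0
otherwise; DEW = (1/c) Σ (den(i) + dw(i)), den = 2e/(n(n−1)) the
intra-cluster edge density, dw = Σ w̄ₑ/(n(n−1)) the weight density
(each undirected edge counted once, so a complete unit-weight cluster
has den = 1 and dw = 0.5). Singleton clusters contribute (0, 0).

Two readings were genuinely open and are both implemented:

* The self-similarity terms i = j are **excluded** from the double sum
  by default. Including them rewards internally sparse clusters —
  sim(I, I) is minimised by an edgeless cluster — directly fighting the
  DEW term; `include_diagonal=True` restores the literal double sum for
  comparison.
* The intra-cluster edge count e in den(i) is read as edges *within*
  cluster i, the only reading that makes den a density in [0, 1] and
  "reflects interaction strength within a cluster".

On the two-triangle test graph (two disjoint unit-weight triangles as
two clusters) the criterion evaluates in closed form to
fval = 0 + 1/1.5 = 2/3, and exhaustive enumeration of all 31
bipartitions confirms the planted split is the unique minimiser.

## Bee-colony center search

The search state is a population of `pop_size` (default 2c) **nectar
sources**, each an ordered set of c distinct node IDs with its
objective value and a trial counter. Per iteration, for every source:

1. **Neighbour move** — one center index is drawn uniformly; the
   replacement is that center's neighbour with the largest "amount of
   information" when a uniform draw exceeds `prob`, otherwise the
   second largest, falling back through the remaining ranking until the
   center set stays distinct ("information" := weighted degree, the
   only per-node quantity an edge list supports, ties broken
   lexicographically). No admissible neighbour → failed search.
2. **Greedy acceptance** — the candidate replaces the source only on a
   strict objective improvement (trial reset to 0); otherwise the trial
   counter increments.
3. **Scout restart** — a source whose trial counter strictly exceeds
   `max_limit` is abandoned for a fresh uniformly random center set.

The best source ever seen (gbest) is tracked; its per-iteration trace
is non-increasing by construction and equals the best initial source
when `maxiter = 0`. One seeded generator drives the whole run, so
results are bit-reproducible from (network, config, seed).

Defaults `prob = 0.4` and `max_limit = 5` are the values at which the
clustering is reported to behave best; `maxiter = 100` suffices for the
30-node benchmark (the trace typically flattens within ~40 iterations).
`pop_size = 1` reproduces a literal single-state search if wanted.

## Baselines

**FCM** (fuzzifier m = 2) is the classic alternating minimisation; to
run it on a graph, nodes are embedded as rows of the normalised
weighted adjacency matrix with Euclidean distances — the minimal
coordinate system an edge list supports. Initial centers are seeded
maximin-style (random first point, then repeatedly the farthest point),
which avoids the symmetric local optimum of two same-clique starting
centers; coincident point/center pairs get crisp membership. Each hard
cluster's center is its member node nearest the FCM centroid.

**Plain IFC** draws random center sets, forms the induced partition,
and keeps the best of `restarts` (default 2c, matching the colony's
population budget) by the same objective — the no-search control for
ABC-IFC.

## Evaluation statistics

Each cluster C is matched to the reference module F maximising
MMS(C, F) = |C ∩ F| (ties: larger module, then name order):
precision = MMS/|C|, recall = MMS/|F|, f-measure their harmonic mean.
Composites are cluster-size-weighted means of precision and recall
(large clusters dominate recall-wise exactly as the
everything-in-one-cluster degenerate solution suggests they should),
combined into the composite f-measure by the harmonic mean.

The enrichment P value is the upper hypergeometric tail
P = Σ_{j=d}^{m} C(D, j) C(M−D, m−j) / C(M, m), computed in log space
(gammaln + logsumexp); structurally impossible terms are skipped. With
no annotation map, the matched reference module plays the function
class: M = |catalog ∪ clustering proteins|, D = |matched module|,
m = |cluster|, d = MMS. With a protein → function-class map, M is the
number of annotated proteins and D the size of the matched module's
dominant class. Both parameterisations are explicit because the
background and class definitions materially change the tail. The
composite P value is the unweighted mean of per-cluster tails.

## Synthetic benchmark

The planted-partition generator emulates the character of a sparse
weighted interactome slice at desk scale: k modules of given sizes,
intra-module edges with probability `p_in` and weights U(w_in),
background edges with probability `p_out` and weights U(w_out), plus an
optional `hub_fraction` of extra degree-preferential edges thickening
the degree tail the way hub proteins do. Defaults — 3 modules × 10
nodes, p_in = 0.9, p_out = 0.05, w_in = U(0.6, 1), w_out = U(0.1, 0.3),
no hub edges — give a strong but not trivial contrast: roughly 9 of 10
intra-module pairs interact strongly, while each node has a ~10% chance
of a weak tie into each foreign module. Weights are uniform rather than
fitted to any empirical distribution; the algorithms only require an
intra/inter weight contrast.

What the generator does *not* emulate: the ~1400-node scale of a real
complex catalog benchmark, overlapping ground-truth modules, unannotated
bystander proteins, and realistic weight distributions. Passing the
planted-recovery tests therefore demonstrates correct mechanics and
sensible relative behaviour of the three algorithms at small scale, not
performance on a real interactome. The 30-node / 10-seed problem size
was chosen so the full benchmark (ABC-IFC + both baselines, ten seeds)
completes in a few seconds.

On this benchmark (seeds 0–9, package defaults) the mean composite
f-measures are: ABC-IFC 0.915, plain IFC 0.813, FCM 1.000, with mean
objective 1.04 (ABC-IFC) vs 1.48 (plain IFC with the same restart
budget). The FCM figure deserves a caveat: with clean block structure
and a full adjacency embedding, maximin-seeded FCM is essentially
spectral-quality — real interactomes, where FCM's embedding is the weak
link, do not reward it this way.

## Numerical choices and edge cases

* Duplicate edges collapse to the maximum weight (order-independent);
  self-loops are dropped and counted; missing weights default to 1.0;
  non-positive weights are rejected.
* Normalised weights are used throughout the membership and objective
  computations for scale invariance; raw weights only feed the
  information (weighted-degree) ranking, which is scale-equivariant.
* Secant solver: start points (0.5, 2.0), ≤ 100 iterations, bisection
  fallback, |g| ≤ 1e-10.
* Ties: argmax assignment → lowest cluster index; neighbour ranking →
  lexicographic node ID; best-match → larger reference module, then
  name; maximin init → lowest point index.
* Exports write floats via `repr` so fixtures round-trip exactly and
  identical runs are byte-identical.

## Known limitations

* No automatic selection of the cluster count c.
* The `as_printed` hesitation convention degrades near-maximal-weight
  node–center ties (see above); use `complement` when recovery matters.
* FCM on networks is sensitive to its embedding; the adjacency-row
  choice is minimal, not optimal.
* The P-value background/class parameterisation without an annotation
  map is a pragmatic stand-in, not a GO enrichment test.
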