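# Methods

This note records the model, the numerical choices and the open design
decisions behind `topocurate`, and states what the synthetic fixtures
do and do not establish.

## Filtration and persistence

The Vietoris–Rips filtration uses the *diameter* convention: a simplex
enters at the maximum pairwise Euclidean distance of its vertices (so
an edge's value is exactly its length).  Simplices with equal value are
ordered by (dimension, lexicographic vertex tuple), which makes the
pairing — and hence every downstream cycle and curation — deterministic
across runs.  Construction is the incremental lower-neighbour clique
expansion; `max_scale` truncates the filtration and is the main
tractability knob (a dimension-3 complex on ~100 points is only
feasible with a capped scale).

Persistence is the standard Z/2 boundary-matrix column reduction with
the youngest-kill convention, with columns stored as Python integers
used as bitmasks (adding two columns is one XOR).  Unlike barcode
libraries, every finite interval carries its creator and destroyer
simplices, which the cycle algorithms require.  Essential (infinite)
intervals are computed but excluded from all cycle extraction; only
finite intervals are localized.

An optional sparse mode prunes edges using a farthest-point greedy
permutation: a point with insertion radius `λ` accepts no edge longer
than `λ(1+ε)/ε`, with `ε = (1−ratio)/ratio` and interleaving ratio
0.9 by default.  It is an approximation for large inputs; the exact
mode is the reference path used by every test.

## Representative cycles

**H1.**  The representative of `[β, δ)` is the creator edge plus the
shortest path between its endpoints through edges inserted strictly
before `β`.  This is the shortest cycle *at birth*; whether it is still
the class that dies at `δ` is not verified (it is in most practical
point-cloud cases), so the H1 representative is a documented
approximation, not a certified minimum for the interval.  Path weights
default to the edge filtration value — identical to the Euclidean
endpoint distance for a Rips filtration, which avoids carrying
coordinates into abstract filtrations — with a unit-hop mode for
complexes where values are not metric.

**Pseudo-manifold conversion.**  The H2 min-cut algorithm needs every
triangle to have at most two tetrahedral cofacets.  Tetrahedra are
scanned in filtration order and kept only while all four of their
triangles still have free cofacet slots.  This greedy rule guarantees
the ≤ 2 invariant globally; where triangles compete for a tetrahedron
it may keep slightly different cofacets than a per-triangle
"first two" reading, which cannot guarantee the invariant at all.

**H2.**  On the pseudo-manifold, the minimal persistent 2-cycle of
`[β, δ)` is exact: build the dual graph (a node per tetrahedron plus
one infinite vertex for boundary triangles, an arc per triangle
between the nodes of its ≤ 2 cofacets), set arc capacity to the
triangle's weight if it entered at or before `β` and +∞ otherwise,
contract the infinite vertex with all tetrahedra inserted after `δ`
into the sink, take the destroyer tetrahedron as source, and return
the triangles dual to a minimum cut.  Infinite capacities are modelled
as uncuttable (networkx treats them as unbounded arcs), never as a
large finite number; parallel arcs are kept distinct by routing each
triangle's arc through its own intermediate node, which leaves the cut
value unchanged.  Triangle weights default to the filtration value;
unit weights are used by the enumeration oracle.  Determinism follows
from the deterministic construction order of the network.

A consequence of the conversion worth stating plainly: trimming
tetrahedra removes fillers, so 2-cycles that die in the full complex
can become essential in the pseudo-manifold, and small unfilled
"bubbles" appear.  The pipeline therefore computes the H2 intervals it
localizes *on the pseudo-manifold itself*, keeping interval and
complex consistent; the localized features are the pseudo-manifold's
finite voids.  On planted spheres these voids still sit on the class
surface, which is what cohort curation needs, but the longest interval
of the full complex (the global cavity) is not necessarily among them.

## Curation rules

A cycle is **dominant** when its most frequent label count reaches
`⌊|Vert(Z)|/2⌋` — the inclusive threshold is forced by the calibration
examples (7 of 15 vertices qualifies).  Among labels tied at the
maximal count the smallest label integer wins; the tie rule is a
determinism choice, nothing more.  The curated cohort set is the union
of dominant-cycle vertex sets over the `k` longest intervals per
requested dimension (`k` defaults to 100), and a cohort appearing in
several cycles is selected once.

**κ** is solved exactly: branch-and-bound (branching on the uncovered
gene with the fewest candidate terms, greedy cover as the incumbent)
determines the optimum size, and the reported witness cover is the
lexicographically least covering term combination of that size.  Cycle
vertex sets are small (~5–30 genes), so exactness is cheap; the greedy
cover is retained only as an upper-bound sanity oracle.  "Not
annotated" is a real, coverable term — the worked six-gene example has
κ = 3 only because the two unannotated genes are covered by it.  The
default selection threshold is `kappa_max = 3` ("low" κ); it is a free
parameter, as no principled cutoff exists.

No scaling is applied to the matrix before the point cloud is built by
default; z-score and log2 transforms are offered because real
expression matrices often need them (a constant column z-scores to
zero rather than erroring).

## Evaluation protocol

"Repeated 80/20 cross-validation" is implemented as Monte-Carlo CV:
`reps` (default 10) independent stratified random splits with 20 %
held out — classic 10-fold would imply 90/10 splits, which is not what
is evaluated here.  Metrics are accuracy (trace/total), macro-averaged
precision and recall (classes never predicted contribute 0), and F1 as
the harmonic mean of the macro precision and recall; the macro
convention is a choice, since multiclass tables are often printed
without one.

When curated and full cohorts are compared, the default protocol
recomputes the curation inside each training split so held-out cohorts
never influence their own selection; `leakage_safe=False` provides the
simpler global-curation variant.  The stricter default is a deliberate
guard — the permutation-null test in the suite checks that no
evaluation path leaks labels.

**CNN.**  The 1-D convolutional classifier (valid convolution, sigmoid;
max-pool 2; inverted dropout 0.25; dense 128 → 64 with ReLU; softmax
output; Adam at 1e-3; minibatch 32; 50 epochs; no early stopping) is a
numpy implementation verified by finite-difference gradient checks.
Inputs are standardized on training statistics inside `fit`.  Genes are
first sorted by their lexicographically smallest annotation term
(stable, so an unannotated input keeps its order), making functionally
related genes contiguous under the convolution kernel.  Filter count,
kernel size, dropout and dense sizes are desk-scale defaults chosen by
manual observation and all exposed.

## Synthetic fixtures: what a green test establishes

The planted-cohort generator emulates classes with geometric structure
(spheres/circles/tori/blobs embedded in the leading coordinates of the
ambient gene space plus isotropic Gaussian noise) and corrupts a fixed
fraction of rows with broad uniform noise *while keeping their class
label* — modelling uncorrelated measurements, the failure mode
dominant-cycle curation can plausibly remove.  Defaults: two radius-3
spheres of 40 cohorts each in 6 ambient dimensions, noise σ = 0.15,
10 % outliers; sizes are chosen for single-CPU tractability of the
dimension-3 Rips complex.  The generator does not emulate platform-
specific microarray noise, heavy-tailed count distributions,
batch structure or class imbalance; recovery results on it establish
that the algorithms find planted geometry and reject uncorrelated
rows, not that any particular real dataset would curate equally well.

All generators are pure functions of their seeds; every randomized
test and the acceptance checks pin those seeds.

## Known limitations

- H1 representatives are shortest-at-birth, not certified minimal for
  the interval (globally minimal cycles are NP-hard).
- H2 localization operates on the pseudo-manifold's finite intervals,
  which are not identical to the full complex's (see above).
- Exact Rips in dimension 3 is exponential in neighbourhood size;
  `max_scale` must be set thoughtfully for more than ~100 points.
- κ's exact solver assumes cycle vertex sets stay small; it is not
  meant for covers over hundreds of genes.
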