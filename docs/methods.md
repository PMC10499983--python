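# Methods

## Scope and model

`dddnet` computes degree-based topological indices

    I(G) = Σ_{uv ∈ E(G)} f(η(u), η(v)),   f symmetric,

for arbitrary simple undirected graphs and, in closed form, for the
dominating David derived network families D1(t), D2(t), D3(t). Two
independent routes to every number are maintained throughout:

1. **brute force** — build the graph, read off degrees, sum edge by edge;
2. **edge partition** — count edges per unordered degree pair (a, b) and
   sum count × f(a, b); for the parametric families the counts are
   quadratics in t and the index becomes a quadratic by exact collection.

The package's central discipline is that the two routes must agree
exactly, and that literature-reported closed forms are *reference data to
be audited*, never silently substituted for derived ones.

## Geometry and coordinates

Hexagons are drawn flat-top with side 2 lattice units. The stored `y`
coordinate is measured in units of √3: a vertex with stored attributes
(x, y) sits at Cartesian (x, y·√3). Because this is an invertible affine
map, straight lines map to straight lines and intersections of segments
with rational stored endpoints have rational stored coordinates. Two
consequences drive the design:

* **no epsilons** — every chord-crossing point in the planarisation step
  is an exact `fractions.Fraction` pair, and coincident crossings merge by
  exact equality (three or more chords through one point collapse into a
  single vertex);
* **horizontality is exact** — an edge is horizontal iff its endpoints
  have equal stored `y`, which is preserved by the map, so the final
  "split each horizontal edge" step needs no angular tolerance.

Vertex identifiers are `(tag, x, y)` tuples, where the tag records
construction origin (`orig`, `mid`, `cross`, `hsplit`, `linker`). They
are a pure function of the construction, so rebuilding any network yields
a bit-identical labelled graph; exports sort lexicographically for stable
diffs.

HC(t) cells are centred at q·(3, 1) + r·(0, 2) for axial coordinates with
max(|q|, |r|, |q+r|) ≤ t − 1, giving the centred arrangement of
3t² − 3t + 1 cells, 6t² vertices and 9t² − 3t edges.

## The six-step pipeline

1. build HC(t);
2. subdivide every edge (midpoint vertices, tag `mid`);
3. in each cell, join the six midpoints that are four steps apart on the
   subdivided 12-cycle — the two overlapping triangles of a hexagram.
   "Distance 4 on the boundary cycle" is adopted as the pairing criterion
   because it is the only reading that produces the hexagram; each cell
   gains exactly 6 chords and no chord is shared between cells;
4. planarise: all pairwise *proper interior* crossings of chords become
   `cross` vertices splitting both chords. Parallel or endpoint-touching
   chord pairs are ignored by construction (an endpoint of a chord lies on
   the cell boundary and no other chord's interior reaches the boundary);
   each hexagram yields exactly 6 crossings and 18 chord segments;
5. delete every `orig` vertex with its incident edges (the honeycomb
   skeleton), an idempotent tag-based filter;
6. subdivide every horizontal edge (`hsplit` vertices), giving DDD(t).

## The derived types and the pair-matching rule

The derived types hinge on a matching among degree-2 `hsplit` vertices.
Two such vertices are **linkable** when they are vertically aligned
exactly one lattice row apart (true distance √3) *and* the open segment
between them passes through no vertex of the graph. The obstruction
clause is what makes the matching perfect and local: the candidate
directly across a cell gap is blocked by the shared edge-midpoint, the
off-centre candidates inside a cell are blocked by hexagram crossings,
leaving one pair per cell (through the hexagram's centre) and two per
vertically adjacent cell pair — (3t² − 3t + 1) + 2(3t² − 5t + 2)
= 9t² − 13t + 5 pairs.

* **D1(t)** joins each pair by an edge (both endpoints reach degree 3);
* **D2(t)** is D1(t) with every degree-3–degree-3 edge subdivided; on
  D1(t) those edges are exactly the pair-joining ones, since linked
  vertices are never adjacent to each other. The operation is implemented
  generically (subdivide all (3,3) edges of any graph) and its partition
  transform — remove E₍₃,₃₎, add 2·E₍₃,₃₎ to E₍₂,₃₎ — is property-tested
  on random graphs;
* **D3(t)** joins each pair by two parallel length-2 paths, so linked
  vertices reach degree 4 and all degrees lie in {2, 4}.

The construction for the derived types is given in the source literature
only as drawings at t = 2; the rule above was reverse-engineered and is
treated as a hypothesis to be *audited*, not assumed: the test suite
compares the partition of every constructed D1/D2/D3 at t = 1..3 against
the parametric tables (they agree exactly), and the count identity
9t² − 13t + 5 is checked per build. Any future disagreement would surface
as a failed comparison, not a silent normalisation.

## Parametric tables and closed forms

The built-in tables store each frequency as an integer-coefficient
quadratic with validity domain t ≥ 1 (the smallest t at which every
frequency is non-negative; non-negativity is verified for t = 1..50, and
evaluation refuses t below the domain or any negative count).

`expand` multiplies each frequency polynomial by f(a, b) and collects
terms in exact integer arithmetic. `fit_from_counts` provides the
independent oracle: exact rational Lagrange interpolation through three
(t, value) points, *certified* against at least one further point — a
nonzero residual flags a non-quadratic sequence rather than returning a
best fit. Certification requires ≥ 4 points by construction.

## The audit

Nine (family, index) combinations are compared: partition-derived
expansion versus the reported closed form, coefficient by coefficient.
Three reported polynomials contradict their own tables —
(D1, F_N*) linear term, (D1, HM_N) linear and constant terms,
(D2, HM_N) linear term — and are flagged with per-coefficient deltas;
the other six match exactly. Two reported typos are handled explicitly:

* the M2* definition is printed in the source as a *sum* of endpoint
  degrees but used as a *product* in every worked computation and in the
  numerical table; the package implements the classical product form and
  records the conflict here and in the index-engine docstring;
* the reported M2*(D3) polynomial prints `1440t^2 - 1872 + 704` with the
  linear term's `t` missing; it is normalised to −1872t for evaluation
  (the only reading consistent with the reported numerical progression)
  while the raw printed string is preserved in the registry.

The two-lineage comparison table (`dddnet verify`, default t = 1..6 to
mirror the published range) carries both values per cell with a match
flag; 18 of 54 cells disagree, exactly the three flagged combinations
across six dimensions.

## Numerical and design choices

* All core arithmetic is `int`/`Fraction`; floats appear only in the
  plotting layer. Coefficient equality is therefore exact, with no
  tolerance parameter anywhere.
* Crossing insertion is a pairwise O(n²) sweep over hexagram chords —
  adequate for this family's size (t = 4 builds in under a second); no
  general segment-intersection engine is attempted.
* Generic graphs without coordinates (fixtures, imported edge lists) get
  deterministic positions on the parabola (i, i²) when a subdivision step
  needs midpoints: chord midpoints of a strictly convex curve are
  pairwise distinct and never coincide with vertices.
* Graph containers are `networkx.Graph`; GraphML export stringifies the
  rational coordinates (`p/q`) and import restores them.
* Problem sizes used by the default test run: constructions up to t = 4
  (route-equivalence checks), honeycomb counting up to t = 5, closed-form
  checks symbolic or at t ≤ 10, table non-negativity to t = 50.

## Limitations

* The pair-matching rule reproduces the published tables for all t and
  the drawings at small t, but drawings are the only independent ground
  truth for the derived types; the rule is audited, not proven.
* Only degree-based indices with integer weights are registered;
  distance-based invariants (Wiener-type) are out of scope.
* The planariser handles exactly the hexagram-chord configuration
  (proper interior crossings of straight chords); it is not a general
  arrangement engine.
* Index values say nothing here about physicochemical correlations; no
  QSPR/QSAR regression is included or claimed.
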