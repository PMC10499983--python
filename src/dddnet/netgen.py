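"""Construction of honeycomb meshes and dominating David derived networks.

The dominating David derived network DDD(t) is built from the honeycomb
mesh HC(t) by a six-step geometric procedure:

1. build HC(t), the centred hexagon-of-hexagons with t cells per side;
2. subdivide every edge once;
3. inside each hexagonal cell join the six new edge-midpoints that are
   four steps apart on the subdivided 12-cycle, producing the two
   overlapping triangles of a hexagram (Star of David);
4. planarise: add a vertex at every point where two hexagram chords
   cross, splitting both chords there;
5. delete the original honeycomb vertices and their incident edges;
6. subdivide every horizontal edge once.

Three derived families follow: D1(t) joins matched pairs of degree-2
split vertices by an edge, D2(t) joins them by a path of length two, and
D3(t) joins them by two parallel paths of length two.  The matching rule
is encoded in :func:`linkable_pairs`.

All coordinates are exact rationals.  Hexagons are drawn flat-top with
side 2 in lattice units, and the stored ``y`` coordinate is measured in
units of sqrt(3): the true Cartesian point of a vertex with attributes
``(x, y)`` is ``(x, y*sqrt(3))``.  This is an affine change of
coordinates, so straight lines stay straight, all hexagram-chord
intersection points have rational stored coordinates, and an edge is
horizontal exactly when its endpoints share a stored ``y``.  Vertex
identifiers are ``(tag, x, y)`` tuples, a pure function of the
construction, so repeated builds yield identical labelled graphs.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Iterable, Sequence

import networkx as nx

__all__ = [
    "GraphStructureError",
    "HexCell",
    "build_honeycomb",
    "subdivide_all_edges",
    "add_star_chords",
    "insert_crossing_vertices",
    "delete_original_skeleton",
    "subdivide_horizontal_edges",
    "build_ddd",
    "linkable_pairs",
    "derive_type1",
    "derive_type2",
    "derive_type3",
    "build_family",
    "FAMILY_BUILDERS",
]

#: vertex origin tags
ORIGINAL = "orig"       # vertex of the starting honeycomb (step 1)
MIDPOINT = "mid"        # edge-subdivision vertex (step 2)
CROSSING = "cross"      # chord-intersection vertex (step 4)
HSPLIT = "hsplit"       # horizontal-edge split vertex (step 6)
LINKER = "linker"       # path vertex introduced by the D2/D3 derivations

# Flat-top hexagon of side 2 centred at the origin, counter-clockwise.
_CORNER_OFFSETS = ((2, 0), (1, 1), (-1, 1), (-2, 0), (-1, -1), (1, -1))
# Axial-neighbour cell centres: basis (3, 1) and (0, 2).
_CELL_BASIS_Q = (3, 1)
_CELL_BASIS_R = (0, 2)


class GraphStructureError(ValueError):
    """Raised when a pipeline step receives a structurally invalid graph."""


HexCell = tuple  # ordered 6-tuple of corner vertex identifiers


def _frac(v) -> Fraction:
    return v if isinstance(v, Fraction) else Fraction(v)


def _vertex(tag: str, x, y) -> tuple:
    return (tag, _frac(x), _frac(y))


def _add_vertex(g: nx.Graph, tag: str, x, y) -> tuple:
    v = _vertex(tag, x, y)
    g.add_node(v, tag=tag, x=v[1], y=v[2])
    return v


def _coords(g: nx.Graph, v) -> tuple[Fraction, Fraction]:
    data = g.nodes[v]
    return data["x"], data["y"]


def _check_dimension(t) -> int:
    if isinstance(t, bool) or not isinstance(t, int):
        raise TypeError(f"dimension t must be an integer, got {t!r}")
    if t < 1:
        raise ValueError(f"dimension t must be >= 1, got {t}")
    return t


# ---------------------------------------------------------------------------
# Step 1 — honeycomb mesh
# ---------------------------------------------------------------------------

def build_honeycomb(t: int) -> tuple[nx.Graph, list[HexCell]]:
    """Build HC(t) and enumerate its hexagonal cells.

    HC(t) is the centred arrangement of 3t^2 - 3t + 1 hexagonal cells with
    t cells along each side; it has 6t^2 vertices (degree 2 or 3) and
    9t^2 - 3t edges.  Cells are listed as ordered 6-cycles of corner
    identifiers, sorted by centre coordinate.
    """
    _check_dimension(t)
    g = nx.Graph()
    cells: list[HexCell] = []
    radius = t - 1
    centres = []
    for q in range(-radius, radius + 1):
        for r in range(-radius, radius + 1):
            if max(abs(q), abs(r), abs(q + r)) <= radius:
                cx = q * _CELL_BASIS_Q[0] + r * _CELL_BASIS_R[0]
                cy = q * _CELL_BASIS_Q[1] + r * _CELL_BASIS_R[1]
                centres.append((cx, cy))
    centres.sort()
    for cx, cy in centres:
        corners = [
            _add_vertex(g, ORIGINAL, cx + dx, cy + dy)
            for dx, dy in _CORNER_OFFSETS
        ]
        for i in range(6):
            g.add_edge(corners[i], corners[(i + 1) % 6])
        cells.append(tuple(corners))
    return g, cells


# ---------------------------------------------------------------------------
# Step 2 — edge subdivision
# ---------------------------------------------------------------------------

def _ensure_positions(g: nx.Graph) -> None:
    """Assign exact synthetic positions to vertices that lack them.

    Generic fixture graphs need not carry coordinates; vertices are placed
    on the parabola (i, i^2) in enumeration order, which guarantees that
    all edge midpoints are distinct and never coincide with a vertex.
    """
    if all("x" in g.nodes[v] for v in g.nodes):
        return
    for i, v in enumerate(g.nodes):
        if "x" not in g.nodes[v]:
            g.nodes[v]["x"] = Fraction(i)
            g.nodes[v]["y"] = Fraction(i * i)
            g.nodes[v].setdefault("tag", ORIGINAL)


def _subdivide_edges(g: nx.Graph, edges: Iterable[tuple], tag: str) -> nx.Graph:
    """Return a copy of ``g`` with each listed edge split at its midpoint."""
    out = g.copy()
    for u, v in edges:
        ux, uy = _coords(g, u)
        vx, vy = _coords(g, v)
        mx, my = (ux + vx) / 2, (uy + vy) / 2
        m = _vertex(tag, mx, my)
        if m in out:
            raise GraphStructureError(
                f"midpoint of edge {u}-{v} collides with existing vertex {m}"
            )
        out.remove_edge(u, v)
        out.add_node(m, tag=tag, x=mx, y=my)
        out.add_edge(u, m)
        out.add_edge(m, v)
    return out


def subdivide_all_edges(g: nx.Graph) -> nx.Graph:
    """Split every edge u-v into u-m-v with a fresh midpoint vertex.

    The result has |V| + |E| vertices and 2|E| edges.
    """
    h = g.copy()
    _ensure_positions(h)
    return _subdivide_edges(h, list(h.edges), MIDPOINT)


# ---------------------------------------------------------------------------
# Step 3 — hexagram chords
# ---------------------------------------------------------------------------

def add_star_chords(g: nx.Graph, cells: Sequence[HexCell]) -> nx.Graph:
    """Join midpoints four steps apart on each cell's subdivided 12-cycle.

    In every hexagonal cell the six midpoint vertices two edges apart are
    joined by straight chords, six per cell, forming the two overlapping
    triangles of a hexagram.  The input must be the step-2 output: each
    cell boundary an alternating original/midpoint 12-cycle.
    """
    out = g.copy()
    for cell in cells:
        if len(cell) != 6:
            raise GraphStructureError(f"cell {cell!r} is not a hexagon")
        mids = []
        for i in range(6):
            u, v = cell[i], cell[(i + 1) % 6]
            ux, uy = _coords(g, u)
            vx, vy = _coords(g, v)
            m = _vertex(MIDPOINT, (ux + vx) / 2, (uy + vy) / 2)
            if m not in g or not (g.has_edge(u, m) and g.has_edge(m, v)):
                raise GraphStructureError(
                    f"cell boundary through {u}-{v} is not a subdivided "
                    "12-cycle; run edge subdivision first"
                )
            mids.append(m)
        for i in range(6):
            out.add_edge(mids[i], mids[(i + 2) % 6])
    return out


# ---------------------------------------------------------------------------
# Step 4 — planarise chord crossings
# ---------------------------------------------------------------------------

def _open_segment_intersection(p, q, a, b):
    """Exact intersection point of open segments pq and ab, or None.

    Parallel (including collinear) segments and intersections at segment
    endpoints return None; only proper interior crossings count.
    """
    rx, ry = q[0] - p[0], q[1] - p[1]
    wx, wy = b[0] - a[0], b[1] - a[1]
    denom = rx * wy - ry * wx
    if denom == 0:
        return None
    dx, dy = a[0] - p[0], a[1] - p[1]
    s = Fraction(dx * wy - dy * wx, denom)
    u = Fraction(dx * ry - dy * rx, denom)
    if not (0 < s < 1 and 0 < u < 1):
        return None
    return (p[0] + s * rx, p[1] + s * ry)


def insert_crossing_vertices(g: nx.Graph) -> nx.Graph:
    """Split hexagram chords at their pairwise intersection points.

    Chords are the midpoint-to-midpoint edges introduced in step 3.  Every
    proper crossing of two chord interiors becomes a vertex at the exact
    rational intersection point; coincident intersection points (three or
    more chords through one point) merge into a single vertex by exact
    coordinate equality.
    """
    chords = [
        (u, v)
        for u, v in g.edges
        if g.nodes[u]["tag"] == MIDPOINT and g.nodes[v]["tag"] == MIDPOINT
    ]
    endpoints = {e: (_coords(g, e[0]), _coords(g, e[1])) for e in chords}
    cuts: dict[tuple, list] = {e: [] for e in chords}
    for i in range(len(chords)):
        for j in range(i + 1, len(chords)):
            pt = _open_segment_intersection(
                *endpoints[chords[i]], *endpoints[chords[j]]
            )
            if pt is not None:
                cuts[chords[i]].append(pt)
                cuts[chords[j]].append(pt)
    out = g.copy()
    for edge, points in cuts.items():
        if not points:
            continue
        (u, v) = edge
        p, q = endpoints[edge]
        # order cut points along the chord; duplicates collapse via set
        ordered = sorted(
            set(points),
            key=lambda pt: (pt[0] - p[0]) * (q[0] - p[0])
            + (pt[1] - p[1]) * (q[1] - p[1]),
        )
        out.remove_edge(u, v)
        chain = [u] + [_add_vertex(out, CROSSING, *pt) for pt in ordered] + [v]
        for a, b in zip(chain, chain[1:]):
            out.add_edge(a, b)
    return out


# ---------------------------------------------------------------------------
# Step 5 — remove the honeycomb skeleton
# ---------------------------------------------------------------------------

def delete_original_skeleton(g: nx.Graph) -> nx.Graph:
    """Remove all original honeycomb vertices and their incident edges."""
    out = g.copy()
    out.remove_nodes_from(
        [v for v in g.nodes if g.nodes[v]["tag"] == ORIGINAL]
    )
    return out


# ---------------------------------------------------------------------------
# Step 6 — split horizontal edges
# ---------------------------------------------------------------------------

def subdivide_horizontal_edges(g: nx.Graph) -> nx.Graph:
    """Subdivide once every edge whose endpoints share a y coordinate."""
    horizontal = [
        (u, v) for u, v in g.edges if _coords(g, u)[1] == _coords(g, v)[1]
    ]
    return _subdivide_edges(g, horizontal, HSPLIT)


# ---------------------------------------------------------------------------
# Full pipeline and the three derived types
# ---------------------------------------------------------------------------

def build_ddd(t: int) -> nx.Graph:
    """Build the dominating David derived network DDD(t), steps 1-6."""
    g, cells = build_honeycomb(t)
    g = subdivide_all_edges(g)
    g = add_star_chords(g, cells)
    g = insert_crossing_vertices(g)
    g = delete_original_skeleton(g)
    g = subdivide_horizontal_edges(g)
    return g


def linkable_pairs(ddd: nx.Graph) -> list[tuple]:
    """Matched pairs of degree-2 split vertices used by the D1/D2/D3 rules.

    Two horizontal-split vertices are paired when they are vertically
    aligned exactly one lattice row apart (true distance sqrt(3)) and the
    open segment between them passes through no vertex of the graph.  The
    obstruction clause is what keeps the matching perfect: the candidate
    directly across a cell gap is blocked by the shared edge-midpoint and
    the off-centre candidates inside a cell are blocked by hexagram
    crossings.  On DDD(t) this yields one pair per cell plus two per
    vertically adjacent cell pair: 9t^2 - 13t + 5 pairs in total.
    """
    occupied = {(_coords(ddd, v)) for v in ddd.nodes}
    splits = {
        _coords(ddd, v): v
        for v in ddd.nodes
        if ddd.nodes[v]["tag"] == HSPLIT and ddd.degree[v] == 2
    }
    pairs = []
    for (x, y), v in sorted(splits.items()):
        partner = splits.get((x, y + 1))
        if partner is None:
            continue
        if (x, y + Fraction(1, 2)) in occupied:
            continue  # blocked by an existing vertex on the segment
        pairs.append((v, partner))
    return pairs


def derive_type1(ddd: nx.Graph) -> nx.Graph:
    """D1(t): join each matched pair of degree-2 split vertices by an edge."""
    out = ddd.copy()
    out.add_edges_from(linkable_pairs(ddd))
    return out


def derive_type2(d1: nx.Graph) -> nx.Graph:
    """D2(t): subdivide once every edge joining two degree-3 vertices.

    Applied to D1(t) this replaces each pair-joining edge by a path of
    length two; the (3,3) edges of D1 are exactly those joining edges.
    """
    h = d1.copy()
    _ensure_positions(h)
    deg = dict(h.degree)
    targets = [(u, v) for u, v in h.edges if deg[u] == 3 and deg[v] == 3]
    return _subdivide_edges(h, targets, LINKER)


def derive_type3(ddd: nx.Graph) -> nx.Graph:
    """D3(t): join each matched pair by two parallel paths of length two.

    Every paired vertex reaches degree 4 and each path gains a fresh
    degree-2 linker vertex, so all degrees of D3(t) lie in {2, 4}.
    """
    out = ddd.copy()
    quarter = Fraction(1, 4)
    for u, v in linkable_pairs(ddd):
        x, y = _coords(ddd, u)
        for dx in (-quarter, quarter):
            w = _add_vertex(out, LINKER, x + dx, y + Fraction(1, 2))
            out.add_edge(u, w)
            out.add_edge(w, v)
    return out


def _build_hc_graph(t: int) -> nx.Graph:
    return build_honeycomb(t)[0]


def _build_d1(t: int) -> nx.Graph:
    return derive_type1(build_ddd(t))


def _build_d2(t: int) -> nx.Graph:
    return derive_type2(derive_type1(build_ddd(t)))


def _build_d3(t: int) -> nx.Graph:
    return derive_type3(build_ddd(t))


FAMILY_BUILDERS = {
    "hc": _build_hc_graph,
    "ddd": build_ddd,
    "d1": _build_d1,
    "d2": _build_d2,
    "d3": _build_d3,
}


def build_family(family: str, t: int) -> nx.Graph:
    """Build a named network family member: hc, ddd, d1, d2 or d3."""
    try:
        builder = FAMILY_BUILDERS[family.lower()]
    except KeyError:
        raise ValueError(
            f"unknown family {family!r}; choose from {sorted(FAMILY_BUILDERS)}"
        ) from None
    return builder(t)
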