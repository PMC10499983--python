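"""Construction pipeline: honeycomb, hexagram steps, derived families."""

from fractions import Fraction

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dddnet import (
    GraphStructureError,
    add_star_chords,
    build_ddd,
    build_family,
    build_honeycomb,
    degree_pair_partition,
    delete_original_skeleton,
    derive_type1,
    derive_type2,
    derive_type3,
    insert_crossing_vertices,
    linkable_pairs,
    subdivide_all_edges,
    subdivide_horizontal_edges,
)
from dddnet.netgen import CROSSING, MIDPOINT


def graphs_equal(a: nx.Graph, b: nx.Graph) -> bool:
    return (
        dict(a.nodes(data=True)) == dict(b.nodes(data=True))
        and set(map(frozenset, a.edges)) == set(map(frozenset, b.edges))
    )


def assert_simple_handshake(g: nx.Graph):
    assert not any(u == v for u, v in g.edges), "self-loop found"
    assert sum(d for _, d in g.degree) == 2 * g.number_of_edges()


@st.composite
def small_graphs(draw):
    n = draw(st.integers(min_value=2, max_value=8))
    possible = [(i, j) for i in range(n) for j in range(i + 1, n)]
    edges = draw(st.lists(st.sampled_from(possible), min_size=1, max_size=12))
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


@pytest.mark.parametrize("t", [1, 2, 3, 4, 5])
def test_honeycomb_counts(t):
    g, cells = build_honeycomb(t)
    assert len(g) == 6 * t * t
    assert g.number_of_edges() == 9 * t * t - 3 * t
    assert len(cells) == 3 * t * t - 3 * t + 1
    assert set(d for _, d in g.degree) <= {2, 3}
    assert all(len(c) == 6 for c in cells)
    assert_simple_handshake(g)


@pytest.mark.parametrize("bad", [0, -3, 2.5, "2", True])
def test_honeycomb_rejects_bad_dimension(bad):
    with pytest.raises((TypeError, ValueError)):
        build_honeycomb(bad)


def test_hc2_partition(fixtures):
    part = degree_pair_partition(fixtures["HC2"])
    assert part.as_dict() == {(2, 2): 6, (2, 3): 12, (3, 3): 12}
    assert part.total_edges == 30


@settings(derandomize=True, max_examples=40)
@given(small_graphs())
def test_subdivision_count_contract(g):
    h = subdivide_all_edges(g)
    assert len(h) == len(g) + g.number_of_edges()
    assert h.number_of_edges() == 2 * g.number_of_edges()
    assert_simple_handshake(h)
    # every new vertex has degree 2
    new = set(h.nodes) - set(g.nodes)
    assert all(h.degree[v] == 2 for v in new)


def test_star_chords_single_hexagon():
    g, cells = build_honeycomb(1)
    s3 = add_star_chords(subdivide_all_edges(g), cells)
    assert len(s3) == 12 and s3.number_of_edges() == 18  # 12 + 6 chords
    chords = [
        (u, v)
        for u, v in s3.edges
        if s3.nodes[u]["tag"] == MIDPOINT and s3.nodes[v]["tag"] == MIDPOINT
    ]
    assert len(chords) == 6
    mids = [v for v in s3.nodes if s3.nodes[v]["tag"] == MIDPOINT]
    assert all(s3.degree[v] == 4 for v in mids)


def test_star_chords_requires_subdivided_boundary():
    g, cells = build_honeycomb(1)
    with pytest.raises(GraphStructureError):
        add_star_chords(g, cells)  # not subdivided


def test_crossings_single_cell():
    g, cells = build_honeycomb(1)
    s4 = insert_crossing_vertices(add_star_chords(subdivide_all_edges(g), cells))
    crossings = [v for v in s4.nodes if s4.nodes[v]["tag"] == CROSSING]
    assert len(crossings) == 6
    assert len(s4) == 18 and s4.number_of_edges() == 30
    assert all(s4.degree[v] == 4 for v in crossings)


def test_crossings_ignore_disjoint_chords():
    g = nx.Graph()
    for i, (x, y) in enumerate([(0, 0), (1, 0), (0, 1), (1, 1)]):
        g.add_node(("mid", Fraction(x), Fraction(y)), tag="mid",
                   x=Fraction(x), y=Fraction(y))
    nodes = list(g.nodes)
    g.add_edge(nodes[0], nodes[1])  # y = 0
    g.add_edge(nodes[2], nodes[3])  # y = 1, parallel: no crossing
    h = insert_crossing_vertices(g)
    assert graphs_equal(g, h)


def test_skeleton_removal_and_idempotence():
    g, cells = build_honeycomb(1)
    s4 = insert_crossing_vertices(add_star_chords(subdivide_all_edges(g), cells))
    s5 = delete_original_skeleton(s4)
    assert len(s5) == 12 and s5.number_of_edges() == 18
    crossings_before = {v for v in s4.nodes if s4.nodes[v]["tag"] == CROSSING}
    assert crossings_before <= set(s5.nodes)  # no crossing removed
    assert graphs_equal(delete_original_skeleton(s5), s5)  # no-op on own output


def test_horizontal_split_counts():
    g, cells = build_honeycomb(2)
    s5 = delete_original_skeleton(
        insert_crossing_vertices(add_star_chords(subdivide_all_edges(g), cells))
    )
    horizontal = [
        (u, v) for u, v in s5.edges
        if s5.nodes[u]["y"] == s5.nodes[v]["y"]
    ]
    s6 = subdivide_horizontal_edges(s5)
    hsplit = [v for v in s6.nodes if s6.nodes[v]["tag"] == "hsplit"]
    assert len(hsplit) == len(horizontal)
    assert s6.number_of_edges() == s5.number_of_edges() + len(horizontal)
    # every remaining horizontal edge has exactly one hsplit endpoint
    for u, v in s6.edges:
        if s6.nodes[u]["y"] == s6.nodes[v]["y"]:
            assert "hsplit" in (s6.nodes[u]["tag"], s6.nodes[v]["tag"])


@pytest.mark.parametrize("t", [1, 2, 3])
def test_ddd_counts_degrees_and_determinism(t, ddd_cache):
    ddd = ddd_cache[t]
    assert ddd.number_of_edges() == 72 * t * t - 72 * t + 24
    assert set(d for _, d in ddd.degree) <= {2, 3, 4}
    assert_simple_handshake(ddd)
    assert graphs_equal(ddd, build_ddd(t))  # bitwise-identical rebuild


@pytest.mark.parametrize("t", [1, 2, 3])
def test_linkable_pair_count(t, ddd_cache):
    pairs = linkable_pairs(ddd_cache[t])
    assert len(pairs) == 9 * t * t - 13 * t + 5
    flat = [v for pair in pairs for v in pair]
    assert len(flat) == len(set(flat))  # perfect matching


@pytest.mark.parametrize("family", ["d1", "d2", "d3"])
@pytest.mark.parametrize("t", [1, 2, 3])
def test_derived_families_match_parametric_tables(family, t, tables, ddd_cache):
    """The audited agreement: built partitions equal the parametric tables."""
    ddd = ddd_cache[t]
    if family == "d1":
        g = derive_type1(ddd)
    elif family == "d2":
        g = derive_type2(derive_type1(ddd))
    else:
        g = derive_type3(ddd)
    assert degree_pair_partition(g).as_dict() == tables[family].evaluate(t).as_dict()
    assert_simple_handshake(g)


def test_d3_degrees_and_edge_count(ddd_cache):
    d3 = derive_type3(ddd_cache[2])
    assert set(d for _, d in d3.degree) == {2, 4}
    assert d3.number_of_edges() == 108 * 4 - 124 * 2 + 44  # 228


def test_type2_subdivides_a_single_33_edge():
    g = nx.Graph()
    g.add_edge("a", "b")
    for leaf in range(2):
        g.add_edge("a", f"al{leaf}")
        g.add_edge("b", f"bl{leaf}")
    before = degree_pair_partition(g).as_dict()
    assert before[(3, 3)] == 1
    h = derive_type2(g)
    after = degree_pair_partition(h).as_dict()
    assert (3, 3) not in after
    assert after[(2, 3)] == before.get((2, 3), 0) + 2
    assert h.number_of_edges() == g.number_of_edges() + 1


@settings(derandomize=True, max_examples=40)
@given(small_graphs())
def test_type2_partition_transform_property(g):
    """Subdividing all (3,3) edges moves their count, doubled, into (2,3)."""
    before = degree_pair_partition(g).as_dict()
    n33 = before.get((3, 3), 0)
    h = derive_type2(g)
    after = degree_pair_partition(h).as_dict()
    assert after.get((3, 3), 0) == 0 or n33 == 0
    assert after.get((2, 3), 0) == before.get((2, 3), 0) + 2 * n33
    assert h.number_of_edges() == g.number_of_edges() + n33
    for pair, n in before.items():
        if pair not in {(3, 3), (2, 3)}:
            assert after.get(pair, 0) == n


def test_symbolic_identity_between_tables(tables):
    """4t-4 + 2(9t^2-13t+5) = 18t^2-22t+6 links the D1 and D2 tables."""
    d1, d2 = tables["d1"], tables["d2"]
    combined = d1.frequency((2, 3)) + d1.frequency((3, 3)).scale(2)
    assert combined == d2.frequency((2, 3))


def test_build_family_dispatch():
    assert build_family("hc", 1).number_of_edges() == 6
    with pytest.raises(ValueError):
        build_family("d9", 1)
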