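"""Graph import/export: tab-separated edge lists and GraphML.

Constructed networks carry exact rational coordinates and origin tags;
both are preserved on export (coordinates as ``p/q`` strings, since
GraphML has no rational type) and restored on GraphML import.  Edge-list
import produces a plain graph with string vertex identifiers, which is
all the generic index engine needs.
"""

from __future__ import annotations

from fractions import Fraction
from pathlib import Path

import networkx as nx

__all__ = [
    "vertex_label",
    "write_edgelist",
    "read_edgelist",
    "write_graphml",
    "read_graphml",
]


def vertex_label(v) -> str:
    """Canonical string form of a vertex identifier."""
    if isinstance(v, tuple) and len(v) == 3:
        tag, x, y = v
        return f"{tag}({x},{y})"
    return str(v)


def _sorted_edges(g: nx.Graph) -> list[tuple[str, str]]:
    edges = []
    for u, v in g.edges:
        a, b = sorted((vertex_label(u), vertex_label(v)))
        edges.append((a, b))
    return sorted(edges)


def write_edgelist(g: nx.Graph, path) -> None:
    """Write a two-column tab-separated edge list with a header line."""
    lines = ["source\ttarget"]
    lines += [f"{a}\t{b}" for a, b in _sorted_edges(g)]
    Path(path).write_text("\n".join(lines) + "\n")


def read_edgelist(path) -> nx.Graph:
    """Read a tab-separated edge list (header line required)."""
    lines = Path(path).read_text().splitlines()
    if not lines or lines[0].split("\t")[:2] != ["source", "target"]:
        raise ValueError(f"{path}: expected a 'source<TAB>target' header line")
    g = nx.Graph()
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise ValueError(f"{path}:{lineno}: expected two tab-separated columns")
        g.add_edge(parts[0], parts[1])
    return g


def _stringified(g: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    for v, data in g.nodes(data=True):
        attrs = {}
        if "tag" in data:
            attrs["tag"] = data["tag"]
        if "x" in data:
            attrs["x"] = str(data["x"])
            attrs["y"] = str(data["y"])
        out.add_node(vertex_label(v), **attrs)
    for u, v in g.edges:
        out.add_edge(vertex_label(u), vertex_label(v))
    return out


def write_graphml(g: nx.Graph, path) -> None:
    """Write GraphML with tag and rational-coordinate attributes."""
    nx.write_graphml(_stringified(g), str(path))


def read_graphml(path) -> nx.Graph:
    """Read GraphML written by :func:`write_graphml`; coordinates become
    :class:`fractions.Fraction` again when present."""
    g = nx.read_graphml(str(path))
    out = nx.Graph()
    for v, data in g.nodes(data=True):
        attrs = dict(data)
        if "x" in attrs:
            attrs["x"] = Fraction(attrs["x"])
            attrs["y"] = Fraction(attrs["y"])
        out.add_node(v, **attrs)
    out.add_edges_from(g.edges)
    return out
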