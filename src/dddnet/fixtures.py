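"""Deterministic small graphs used by examples and the test suite."""

from __future__ import annotations

import networkx as nx

from .netgen import build_honeycomb

__all__ = ["fixture_graphs"]


def fixture_graphs() -> dict[str, nx.Graph]:
    """Named small graphs: paths, cycles, stars, cliques, honeycombs.

    All are plain networkx graphs with integer vertex labels except the
    honeycomb entries, which carry exact coordinates and origin tags.
    """
    return {
        "P2": nx.path_graph(2),
        "P4": nx.path_graph(4),
        "C6": nx.cycle_graph(6),
        "C12": nx.cycle_graph(12),
        "S4": nx.star_graph(4),
        "K4": nx.complete_graph(4),
        "K5": nx.complete_graph(5),
        "hexagon": nx.cycle_graph(6),
        "HC1": build_honeycomb(1)[0],
        "HC2": build_honeycomb(2)[0],
    }
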