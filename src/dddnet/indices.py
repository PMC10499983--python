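"""Degree-based topological indices with a pluggable weight registry.

A degree-based topological index of a simple graph G is

    I(G) = sum over edges uv of f(deg(u), deg(v))

for a symmetric weight function f.  Three classical indices are built in:

* ``fn`` — forgotten index F_N*, f(a, b) = a^2 + b^2
* ``m2`` — second Zagreb index M2*, f(a, b) = a * b
* ``hm`` — hyper-Zagreb index HM_N, f(a, b) = (a + b)^2

All arithmetic is exact integer arithmetic.  An index can be computed
either edge-by-edge from a graph or from a degree-pair partition; the two
routes agree by construction and the test suite holds them to it.

Note on M2*: some published accounts print its definition with a sum
``deg(u) + deg(v)`` of endpoint degrees, yet carry out every worked
computation with the product.  This package implements the classical
product form, which is the only one consistent with the published
numerical tables; the closed-form audit records the conflict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import networkx as nx

from .partition import DegreePairPartition, degree_pair_partition

__all__ = [
    "IndexDefinition",
    "IndexRegistry",
    "registry",
    "index_from_partition",
    "index_from_graph",
]


@dataclass(frozen=True)
class IndexDefinition:
    """A named symmetric weight function on degree pairs."""

    key: str
    display_name: str
    weight: Callable[[int, int], int]
    description: str = ""

    def __call__(self, a: int, b: int) -> int:
        return self.weight(a, b)


class IndexRegistry:
    """Mutable collection of index definitions, keyed by short name."""

    def __init__(self) -> None:
        self._defs: dict[str, IndexDefinition] = {}

    def register(self, definition: IndexDefinition) -> IndexDefinition:
        if definition.key in self._defs:
            raise ValueError(f"index {definition.key!r} already registered")
        for a in range(1, 11):
            for b in range(a, 11):
                if definition.weight(a, b) != definition.weight(b, a):
                    raise ValueError(
                        f"weight of {definition.key!r} is not symmetric "
                        f"at ({a},{b})"
                    )
        self._defs[definition.key] = definition
        return definition

    def __getitem__(self, key: str) -> IndexDefinition:
        try:
            return self._defs[key]
        except KeyError:
            raise KeyError(
                f"unknown index {key!r}; choose from {sorted(self._defs)}"
            ) from None

    def __contains__(self, key: str) -> bool:
        return key in self._defs

    def __iter__(self):
        return iter(self._defs.values())

    def keys(self):
        return sorted(self._defs)


def _default_registry() -> IndexRegistry:
    reg = IndexRegistry()
    reg.register(
        IndexDefinition(
            "fn",
            "F_N*",
            lambda a, b: a * a + b * b,
            "forgotten index: sum of squared endpoint degrees",
        )
    )
    reg.register(
        IndexDefinition(
            "m2",
            "M2*",
            lambda a, b: a * b,
            "second Zagreb index: product of endpoint degrees",
        )
    )
    reg.register(
        IndexDefinition(
            "hm",
            "HM_N",
            lambda a, b: (a + b) ** 2,
            "hyper-Zagreb index: squared sum of endpoint degrees",
        )
    )
    return reg


_REGISTRY = _default_registry()


def registry() -> IndexRegistry:
    """The process-wide index registry (fn, m2, hm plus user additions)."""
    return _REGISTRY


def _resolve(d) -> IndexDefinition:
    return _REGISTRY[d] if isinstance(d, str) else d


def index_from_partition(p: DegreePairPartition, d) -> int:
    """Sum of count * f(a, b) over a degree-pair partition, exactly."""
    d = _resolve(d)
    return sum(n * d(a, b) for (a, b), n in p)


def index_from_graph(g: nx.Graph, d) -> int:
    """Edge-by-edge index computation on a simple graph.

    Always equals ``index_from_partition(degree_pair_partition(g), d)``.
    """
    d = _resolve(d)
    deg = dict(g.degree)
    return sum(d(deg[u], deg[v]) for u, v in g.edges)
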