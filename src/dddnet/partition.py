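"""Degree-pair edge partitions, concrete and parametric.

The edge partition E_{a,b} of a graph counts, for every unordered pair of
vertex degrees (a, b) with a <= b, the edges whose endpoints have those
degrees.  It is the central bookkeeping device for degree-based
topological indices: the index value is a weighted sum over the partition.

For the three dominating David derived families the partitions are known
in closed form as quadratics in the dimension t; those parametric tables
are shipped here as first-class data (:func:`builtin_tables`).
"""

from __future__ import annotations

import csv
import io
import json
from collections import Counter
from dataclasses import dataclass

import networkx as nx

from .polynomials import QuadraticPolynomial

__all__ = [
    "DegreePairPartition",
    "ParametricPartition",
    "degree_pair_partition",
    "builtin_tables",
    "evaluate_parametric",
]


@dataclass(frozen=True)
class DegreePairPartition:
    """Multiset of unordered degree pairs (a, b), a <= b, with edge counts."""

    counts: tuple  # sorted tuple of ((a, b), count)

    @staticmethod
    def from_mapping(mapping) -> "DegreePairPartition":
        items = []
        for (a, b), n in mapping.items():
            if a > b:
                a, b = b, a
            if n < 0:
                raise ValueError(f"negative count for pair ({a},{b}): {n}")
            if n:
                items.append(((a, b), n))
        items.sort()
        keys = [k for k, _ in items]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate degree pair after normalisation")
        return DegreePairPartition(tuple(items))

    def as_dict(self) -> dict:
        return dict(self.counts)

    @property
    def total_edges(self) -> int:
        return sum(n for _, n in self.counts)

    def __getitem__(self, pair) -> int:
        a, b = min(pair), max(pair)
        return self.as_dict().get((a, b), 0)

    def __iter__(self):
        return iter(self.counts)

    def to_csv(self) -> str:
        buf = io.StringIO()
        writer = csv.writer(buf, lineterminator="\n")
        writer.writerow(["a", "b", "count"])
        for (a, b), n in self.counts:
            writer.writerow([a, b, n])
        return buf.getvalue()

    @staticmethod
    def from_csv(text: str) -> "DegreePairPartition":
        reader = csv.DictReader(io.StringIO(text))
        return DegreePairPartition.from_mapping(
            {
                (int(row["a"]), int(row["b"])): int(row["count"])
                for row in reader
            }
        )


def degree_pair_partition(g: nx.Graph) -> DegreePairPartition:
    """Tally (min(deg u, deg v), max(deg u, deg v)) over all edges of ``g``."""
    deg = dict(g.degree)
    tally = Counter()
    for u, v in g.edges:
        a, b = deg[u], deg[v]
        tally[(min(a, b), max(a, b))] += 1
    return DegreePairPartition.from_mapping(tally)


@dataclass(frozen=True)
class ParametricPartition:
    """Edge partition of a one-parameter graph family.

    Each entry maps a degree pair to a quadratic-in-t frequency with
    integer coefficients.  Valid for integer ``t >= min_t``.
    """

    family: str
    entries: tuple  # sorted tuple of ((a, b), QuadraticPolynomial)
    min_t: int = 1

    def pairs(self):
        return [pair for pair, _ in self.entries]

    def frequency(self, pair) -> QuadraticPolynomial:
        a, b = min(pair), max(pair)
        for key, poly in self.entries:
            if key == (a, b):
                return poly
        return QuadraticPolynomial.zero()

    def evaluate(self, t: int) -> DegreePairPartition:
        return evaluate_parametric(self, t)

    def edge_count_polynomial(self) -> QuadraticPolynomial:
        total = QuadraticPolynomial.zero()
        for _, poly in self.entries:
            total = total + poly
        return total

    def to_json(self) -> str:
        return json.dumps(
            {
                "family": self.family,
                "min_t": self.min_t,
                "entries": [
                    {"a": a, "b": b, "coefficients": list(poly.coefficients)}
                    for (a, b), poly in self.entries
                ],
            },
            indent=2,
        )

    @staticmethod
    def from_json(text: str) -> "ParametricPartition":
        data = json.loads(text)
        entries = tuple(
            sorted(
                (
                    (
                        (e["a"], e["b"]),
                        QuadraticPolynomial(*e["coefficients"]),
                    )
                    for e in data["entries"]
                ),
            )
        )
        return ParametricPartition(data["family"], entries, data["min_t"])


def evaluate_parametric(p: ParametricPartition, t: int) -> DegreePairPartition:
    """Evaluate every frequency polynomial of ``p`` at integer ``t``.

    A negative evaluated frequency signals a ``t`` outside the family's
    validity domain and raises ``ValueError``.
    """
    if isinstance(t, bool) or not isinstance(t, int):
        raise TypeError(f"t must be an integer, got {t!r}")
    if t < p.min_t:
        raise ValueError(
            f"t={t} below the validity domain of {p.family} (t >= {p.min_t})"
        )
    counts = {}
    for pair, poly in p.entries:
        n = poly(t)
        if n < 0:
            raise ValueError(
                f"{p.family}: frequency of {pair} is negative at t={t}"
            )
        counts[pair] = n
    return DegreePairPartition.from_mapping(counts)


def _table(family: str, rows) -> ParametricPartition:
    entries = tuple(
        sorted((pair, QuadraticPolynomial(*coeffs)) for pair, coeffs in rows)
    )
    return ParametricPartition(family=family, entries=entries, min_t=1)


def builtin_tables() -> dict[str, ParametricPartition]:
    """The published parametric edge partitions of D1(t), D2(t), D3(t)."""
    return {
        "d1": _table(
            "d1",
            [
                ((2, 2), (0, 4, 0)),
                ((2, 3), (0, 4, -4)),
                ((2, 4), (0, 28, -16)),
                ((3, 3), (9, -13, 5)),
                ((3, 4), (36, -56, 24)),
                ((4, 4), (36, -52, 20)),
            ],
        ),
        "d2": _table(
            "d2",
            [
                ((2, 2), (0, 4, 0)),
                ((2, 3), (18, -22, 6)),
                ((2, 4), (0, 28, -16)),
                ((3, 4), (36, -56, 24)),
                ((4, 4), (36, -52, 20)),
            ],
        ),
        "d3": _table(
            "d3",
            [
                ((2, 2), (0, 4, 0)),
                ((2, 4), (36, -20, 0)),
                ((4, 4), (72, -108, 44)),
            ],
        ),
    }
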