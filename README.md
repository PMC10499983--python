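# dddnet

Exact construction of **dominating David derived networks** and exact
computation of their degree-based topological indices.

## The problem

Degree-based topological indices are graph invariants of the form

    I(G) = Σ_{uv ∈ E(G)} f(η(u), η(v))

where η(v) is the degree of vertex v. They are widely used as molecular
descriptors in QSPR/QSAR modelling. For one-parameter graph families the
standard route to a closed form is the *edge partition method*: count the
edges E_{a,b} with endpoint degrees (a, b) as polynomials in the family
dimension t, weight each count by f(a, b), and collect terms.

The dominating David derived network family is built from the honeycomb
mesh HC(t) — the centred hexagon-of-hexagons with t cells per side — by
subdividing every edge, drawing the hexagram (Star of David) chords inside
each cell, planarising the chord crossings, deleting the original
honeycomb skeleton, and splitting each horizontal edge. Three derived
types follow by linking matched pairs of degree-2 split vertices: **D1(t)**
links each pair with an edge, **D2(t)** with a path of length two, and
**D3(t)** with two parallel paths of length two.

Closed forms for three indices on these families have been reported in the
literature together with parametric edge-partition tables:

* forgotten index `F_N*`, f(a, b) = a² + b²
* second Zagreb index `M2*`, f(a, b) = a·b
* hyper-Zagreb index `HM_N`, f(a, b) = (a + b)²

Three of the nine reported polynomials are inconsistent with the very
tables they were derived from. This package treats the partition-derived
polynomials as canonical, keeps the reported ones as reference data, and
**audits** the two against each other instead of silently correcting
either side. Everything — coordinates, partitions, indices, polynomial
algebra — is exact rational/integer arithmetic; there is no floating point
in the core and no tolerance anywhere.

## Worked example

```python
>>> from dddnet import (build_family, degree_pair_partition, builtin_tables,
...                     index_from_partition, expand, audit)
>>> d1 = build_family("d1", 2)            # exact geometric construction
>>> degree_pair_partition(d1).as_dict()
{(2, 2): 8, (2, 3): 4, (2, 4): 40, (3, 3): 15, (3, 4): 56, (4, 4): 60}
>>> tables = builtin_tables()
>>> tables["d1"].evaluate(2).as_dict() == degree_pair_partition(d1).as_dict()
True
>>> index_from_partition(tables["d2"].evaluate(1), "fn")
526
>>> str(expand(tables["d1"], "fn"))
'2214t^2 - 2654t + 958'
>>> [(r.family, r.index_key) for r in audit() if not r.matches]
[('d1', 'fn'), ('d1', 'hm'), ('d2', 'hm')]
```

The first lines show that the brute-force construction of D1(2) reproduces
the parametric partition table exactly (183 edges in six degree classes).
`526` is the forgotten index of D2(1). The expansion of the D1 table gives
the linear coefficient −2654, whereas the reported closed form prints
−1951 — one of the three combinations the audit flags; for the other six
the expansion matches the report coefficient for coefficient.

The same results from the command line:

```
$ dddnet index --family d2 --t 1 --index fn --from table
526
$ dddnet closedform --family d1 --index fn --source table
{"family": "d1", "index": "fn", "source": "table", "c2": 2214, "c1": -2654, "c0": 958}
$ dddnet audit --out audit.csv        # 9-row derived-vs-reported comparison
$ dddnet verify --t-max 6 --out comparison.csv --plot comparison.png
wrote comparison.csv; 18 mismatching cells flagged
```

`verify` reproduces the published numerical comparison for t = 1..6 with
both lineages (partition-derived and reported-polynomial) side by side;
the 18 flagged cells are exactly the three inconsistent (family, index)
combinations across six dimensions.

## Layout

| module | contents |
|---|---|
| `dddnet.netgen` | honeycomb + six-step pipeline + D1/D2/D3 derivations, exact rational geometry |
| `dddnet.partition` | degree-pair partitions, built-in parametric tables, CSV/JSON |
| `dddnet.indices` | index registry (`fn`, `m2`, `hm`, user-extensible), both computation routes |
| `dddnet.polynomials` | exact quadratic algebra and certified interpolation |
| `dddnet.closedform` | expansion, fitting, reported-polynomial registry, audit |
| `dddnet.report` | two-lineage comparison table and plot |
| `dddnet.graphio` | edge-list / GraphML import-export |
| `dddnet.cli` | `dddnet` command-line shell |

See `docs/methods.md` for the construction conventions, the pair-matching
rule behind the derived types, and known limitations.
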