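"""Median-joining networks for multistate STR haplotypes.

Preprocessing follows the conventional Network-program workflow for Y-STR
input: microvariant alleles are rounded to the nearest integer (half away
from zero), the constitutively duplicated DYS385 a/b locus is excluded, and
the code 99 / blank cells are treated as missing (a missing locus is simply
excluded from any comparison involving it).

The per-locus step distance between haplotypes is |a − b| (single-repeat
mutational steps, uniform locus weights by default).  The construction is
Bandelt's scheme specialised to ordered characters:

1. build the ε-relaxed minimum spanning network (MSN) over the current node
   set — an edge (u,v) belongs to the network iff its weight is within ε of
   the bottleneck (minimax-path) distance between u and v, so ε = 0 yields
   the union of all MSTs;
2. for every connected triple in the MSN compute the locus-wise median
   vector (the statistical median of three integers generalises the binary
   majority rule), and add median vectors whose inclusion lowers the
   network's connection cost (the MST total over the node set);
3. repeat until no median helps, then prune median nodes whose removal
   leaves the connection cost unchanged.

All tie-breaks are lexicographic on haplotype vectors, so the construction
is deterministic and seed-free.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .haplotype_io import HaplotypeTable

logger = logging.getLogger(__name__)

Vector = tuple  # of int | None (None = missing)


def step_distance(u: Vector, v: Vector, weights=None) -> float:
    """Σ per-locus w·|a − b| over loci present in both vectors."""
    total = 0.0
    for i, (a, b) in enumerate(zip(u, v)):
        if a is None or b is None:
            continue
        w = 1.0 if weights is None else weights[i]
        total += w * abs(a - b)
    return total


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class ReducedHaplotypes:
    """Network input: integer haplotypes with multiplicities and members."""

    vectors: tuple[Vector, ...]
    multiplicities: tuple[int, ...]
    loci: tuple[str, ...]
    members: tuple[tuple[str, ...], ...]  # sample ids collapsed into each vector


def prepare_network_input(table: HaplotypeTable) -> ReducedHaplotypes:
    """Drop multi-copy loci, round alleles to integers, collapse duplicates.

    Haplotypes at mutual step distance 0 (identical up to missing data) are
    collapsed together so every network edge has positive weight.
    """
    loci = tuple(l for l in table.panel.loci if l not in table.panel.multi_copy)
    raw: list[tuple[Vector, str]] = []
    for p in table.profiles:
        vec = []
        for locus in loci:
            a = p.alleles[locus][0]
            vec.append(None if a.missing else _round_half_away(a.value))
        raw.append((tuple(vec), p.sample_id))
    # collapse identical vectors first, then merge distance-0 groups
    groups: dict[Vector, list[str]] = {}
    for vec, sid in raw:
        groups.setdefault(vec, []).append(sid)
    reps = sorted(groups, key=_lex_key)  # lexicographic; missing sorts last
    merged: list[tuple[Vector, list[str]]] = []
    for vec in reps:
        for mvec, members in merged:
            if step_distance(vec, mvec) == 0:
                members.extend(groups[vec])
                break
        else:
            merged.append((vec, list(groups[vec])))
    return ReducedHaplotypes(
        vectors=tuple(v for v, _ in merged),
        multiplicities=tuple(len(m) for _, m in merged),
        loci=loci,
        members=tuple(tuple(m) for _, m in merged),
    )


def _distance_matrix(vectors, weights=None) -> np.ndarray:
    n = len(vectors)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        D[i, j] = D[j, i] = step_distance(vectors[i], vectors[j], weights)
    return D


def _mst_cost(D: np.ndarray) -> float:
    from scipy.sparse.csgraph import minimum_spanning_tree

    if len(D) < 2:
        return 0.0
    return float(minimum_spanning_tree(D).sum())


def msn(vectors, epsilon: float = 0.0, weights=None) -> nx.Graph:
    """ε-relaxed minimum spanning network over haplotype vectors.

    Edge (u,v) is included iff w(u,v) ≤ bottleneck(u,v) + ε, where the
    bottleneck distance is the max edge on the MST path (the threshold at
    which u and v join in Kruskal's construction).  ε = 0 gives the union of
    all MSTs; large ε tends to the complete graph.
    """
    n = len(vectors)
    G = nx.Graph()
    G.add_nodes_from(range(n))
    if n < 2:
        return G
    D = _distance_matrix(vectors, weights)
    T = nx.minimum_spanning_tree(
        nx.from_numpy_array(D), weight="weight", algorithm="kruskal"
    )
    # bottleneck distances via the unique MST path
    for i in range(n):
        # single-source max-edge along tree paths
        bottleneck = {i: 0.0}
        stack = [i]
        seen = {i}
        while stack:
            u = stack.pop()
            for v in T.neighbors(u):
                if v in seen:
                    continue
                seen.add(v)
                bottleneck[v] = max(bottleneck[u], T[u][v]["weight"])
                stack.append(v)
        for j in range(i + 1, n):
            if D[i, j] <= bottleneck[j] + epsilon + 1e-9:
                G.add_edge(i, j, weight=D[i, j])
    return G


def _median_vector(u: Vector, v: Vector, w: Vector) -> Vector:
    """Locus-wise median of a triple; missing copied from the majority."""
    out = []
    for a, b, c in zip(u, v, w):
        present = [x for x in (a, b, c) if x is not None]
        if not present:
            out.append(None)
        elif len(present) == 3:
            out.append(int(sorted(present)[1]))
        else:
            vals = sorted(set(present))
            if len(vals) == 1:
                out.append(int(vals[0]))
            else:  # two present, unequal: no majority -> missing
                out.append(None)
    return tuple(out)


@dataclass(frozen=True)
class NetNode:
    name: str
    vector: Vector
    kind: str  # "observed" | "median"
    size: int
    annotation: tuple[str, ...] = ()


@dataclass(frozen=True)
class HaploNetwork:
    nodes: tuple[NetNode, ...]
    edges: tuple[tuple[int, int, float], ...]
    epsilon: float
    total_length: float  # MST cost over the final node set

    @property
    def graph(self) -> nx.Graph:
        G = nx.Graph()
        for i, n in enumerate(self.nodes):
            G.add_node(
                i,
                name=n.name,
                kind=n.kind,
                size=n.size,
                haplogroup=",".join(n.annotation),
                vector=" ".join("?" if x is None else str(x) for x in n.vector),
            )
        for i, j, w in self.edges:
            G.add_edge(i, j, weight=w)
        return G


def median_joining(
    reduced: ReducedHaplotypes,
    epsilon: float = 0.0,
    weights=None,
    max_generations: int = 12,
) -> HaploNetwork:
    """Median-joining network over reduced haplotypes.

    Raises RuntimeError if median generations exceed ``max_generations``
    (non-termination guard).
    """
    observed = list(reduced.vectors)
    if len(observed) == 1:
        node = NetNode("H1", observed[0], "observed", reduced.multiplicities[0])
        return HaploNetwork((node,), (), epsilon, 0.0)
    medians: list[Vector] = []
    known = set(observed)

    def current_cost(extra: Vector | None = None) -> float:
        vecs = observed + medians + ([extra] if extra is not None else [])
        return _mst_cost(_distance_matrix(vecs, weights))

    cost = current_cost()
    for generation in range(max_generations + 1):
        if generation == max_generations:
            raise RuntimeError("median-joining did not terminate within the cap")
        net = msn(observed + medians, epsilon, weights)
        # connected triples: two edges sharing a node
        candidates: set[Vector] = set()
        vecs = observed + medians
        for u in net.nodes:
            nbrs = sorted(net.neighbors(u))
            for v, w in itertools.combinations(nbrs, 2):
                m = _median_vector(vecs[u], vecs[v], vecs[w])
                if m not in known:
                    candidates.add(m)
        improved = False
        while candidates:
            scored = []
            for m in candidates:
                c = current_cost(m)
                if c < cost - 1e-9:
                    scored.append((c, m))
            if not scored:
                break
            scored.sort(key=lambda t: (t[0], _lex_key(t[1])))
            best_cost, best = scored[0]
            medians.append(best)
            known.add(best)
            candidates.discard(best)
            cost = best_cost
            improved = True
        if not improved:
            break
    # prune median vectors whose removal leaves the connection cost unchanged
    changed = True
    while changed:
        changed = False
        for m in sorted(medians, key=_lex_key):
            trial = [x for x in medians if x != m]
            c = _mst_cost(_distance_matrix(observed + trial, weights))
            if c <= cost + 1e-9:
                medians = trial
                cost = c
                changed = True
                break
    vecs = observed + medians
    net = msn(vecs, epsilon, weights)
    nodes = []
    for i, v in enumerate(vecs):
        if i < len(observed):
            nodes.append(NetNode(f"H{i+1}", v, "observed", reduced.multiplicities[i]))
        else:
            nodes.append(NetNode(f"mv{i - len(observed) + 1}", v, "median", 0))
    edges = tuple(
        (min(i, j), max(i, j), float(net[i][j]["weight"])) for i, j in net.edges
    )
    return HaploNetwork(tuple(nodes), edges, epsilon, cost)


def _lex_key(vec: Vector):
    return tuple((x is None, x if x is not None else 0) for x in vec)


def annotate_haplogroups(net: HaploNetwork, model, loci) -> HaploNetwork:
    """Annotate observed nodes with predicted haplogroup labels (ties kept)."""
    from dataclasses import replace

    from .ancestry import predict_from_values

    new_nodes = []
    for node in net.nodes:
        if node.kind != "observed":
            new_nodes.append(node)
            continue
        values = {l: v for l, v in zip(loci, node.vector) if v is not None}
        ranked = predict_from_values(values, model)
        top = ranked[0][1]
        labels = tuple(h for h, p in ranked if abs(p - top) < 1e-9)
        new_nodes.append(replace(node, annotation=labels))
    return HaploNetwork(tuple(new_nodes), net.edges, net.epsilon, net.total_length)


def export_network(net: HaploNetwork, path, fmt: str = "graphml") -> None:
    """Write the network as GraphML or DOT (node attrs: size, kind, label)."""
    G = net.graph
    if fmt == "graphml":
        nx.write_graphml(G, path)
    elif fmt == "dot":
        lines = ["graph haplonetwork {"]
        for i, data in G.nodes(data=True):
            lines.append(
                f'  n{i} [label="{data["name"]}", kind="{data["kind"]}", '
                f'size={data["size"]}, haplogroup="{data["haplogroup"]}"];'
            )
        for i, j, data in G.edges(data=True):
            lines.append(f'  n{i} -- n{j} [label="{data["weight"]:g}", weight={data["weight"]:g}];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
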