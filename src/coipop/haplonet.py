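"""Median-joining haplotype networks.

Implements the median-joining algorithm of Bandelt, Forster & Roehl
(1999) over collapsed haplotypes: restrict to segregating columns, build
the epsilon-relaxed minimum-spanning network (the union of all minimum
spanning trees at epsilon = 0), propose median (Steiner) vectors from
connected node triples, add the median that most reduces the spanning
cost, iterate to a fixpoint, and finally prune median vectors that lie
on no shortest connection between observed haplotypes.

All tie-breaks are by lexicographic sequence order, so the network is
deterministic across runs and platforms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .errors import ConfigurationError, DataError

__all__ = [
    "NetworkNode",
    "HaplotypeNetwork",
    "hamming",
    "hamming_matrix",
    "median_joining",
    "export_network",
    "import_graphml",
    "edge_cut_groups",
]


@dataclass(frozen=True)
class NetworkNode:
    node_id: str
    sequence: str  # over the segregating columns used by the network
    kind: str  # "observed" | "median"
    size: int  # specimen frequency; 0 for medians
    traits: tuple[tuple[str, int], ...] = ()  # (group label, count)


@dataclass(frozen=True)
class HaplotypeNetwork:
    nodes: tuple[NetworkNode, ...]
    edges: tuple[tuple[str, str, int], ...]  # (node_a, node_b, mutations)
    epsilon: int
    segregating_columns: tuple[int, ...] = ()

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        for node in self.nodes:
            g.add_node(
                node.node_id,
                sequence=node.sequence,
                kind=node.kind,
                size=node.size,
                traits=json.dumps(dict(node.traits)),
            )
        for a, b, w in self.edges:
            g.add_edge(a, b, weight=w)
        return g


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise DataError("hamming distance requires equal-length sequences")
    return sum(x != y for x, y in zip(a, b))


def hamming_matrix(haplotypes: list[str]) -> list[list[int]]:
    """Symmetric pairwise Hamming distance matrix (differing columns)."""
    n = len(haplotypes)
    mat = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming(haplotypes[i], haplotypes[j])
            mat[i][j] = mat[j][i] = d
    return mat


# ---------------------------------------------------------------------------
# internal spanning-structure machinery (operates on a list of sequences)
# ---------------------------------------------------------------------------

def _sorted_edges(seqs: list[str]):
    n = len(seqs)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            edges.append((hamming(seqs[i], seqs[j]), i, j))
    edges.sort()
    return edges


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[rb] = ra
        return True


def _mst(seqs: list[str]) -> tuple[int, list[tuple[int, int, int]]]:
    """Kruskal MST; returns (total cost, edges (i, j, w))."""
    dsu = _DSU(len(seqs))
    cost = 0
    chosen = []
    for w, i, j in _sorted_edges(seqs):
        if dsu.union(i, j):
            cost += w
            chosen.append((i, j, w))
    return cost, chosen


def _bottleneck(seqs: list[str]) -> list[list[int]]:
    """Minimax (bottleneck) pairwise distances, from an MST."""
    n = len(seqs)
    _, mst_edges = _mst(seqs)
    adj: list[list[tuple[int, int]]] = [[] for _ in range(n)]
    for i, j, w in mst_edges:
        adj[i].append((j, w))
        adj[j].append((i, w))
    bott = [[0] * n for _ in range(n)]
    for src in range(n):
        seen = {src}
        stack = [(src, 0)]
        while stack:
            u, mx = stack.pop()
            for v, w in adj[u]:
                if v not in seen:
                    seen.add(v)
                    bott[src][v] = max(mx, w)
                    stack.append((v, max(mx, w)))
    return bott


def _msn_edges(seqs: list[str], epsilon: int) -> list[tuple[int, int, int]]:
    """Epsilon-relaxed minimum-spanning-network edges.

    An edge (i, j) is admitted when d(i, j) <= bottleneck(i, j) + epsilon;
    at epsilon = 0 this is exactly the union of all minimum spanning trees.
    """
    bott = _bottleneck(seqs)
    edges = []
    n = len(seqs)
    for i in range(n):
        for j in range(i + 1, n):
            d = hamming(seqs[i], seqs[j])
            if d <= bott[i][j] + epsilon:
                edges.append((i, j, d))
    return edges


def _median(u: str, v: str, w: str) -> str:
    """Per-column majority of three sequences.

    Where all three states differ there is no majority; the state of the
    first sequence in processing order is kept.
    """
    out = []
    for a, b, c in zip(u, v, w):
        if b == c:
            out.append(b)
        else:
            out.append(a)  # a==b, a==c, or all distinct -> keep first
    return "".join(out)


def median_joining(
    haplotypes: list[str],
    frequencies: list[int] | None = None,
    epsilon: int = 0,
    trait_table: dict[str, dict[str, int]] | None = None,
    ids: list[str] | None = None,
) -> HaplotypeNetwork:
    """Build a median-joining network from distinct haplotype sequences.

    ``haplotypes`` are equal-length representative sequences (one per
    haplotype); ``frequencies`` the specimen counts (default 1 each);
    ``trait_table`` maps haplotype id to a {group label: count} composition
    carried through to the nodes.  The algorithm iterates median addition
    until the spanning cost over the node set stops decreasing; each
    accepted median strictly decreases an integer cost, so it terminates.
    """
    if not haplotypes:
        raise DataError("median_joining requires at least one haplotype")
    if epsilon < 0 or int(epsilon) != epsilon:
        raise DataError("epsilon must be a non-negative integer")
    if len(set(haplotypes)) != len(haplotypes):
        raise DataError("haplotype sequences must be distinct; collapse first")
    L = {len(s) for s in haplotypes}
    if len(L) > 1:
        raise DataError("haplotypes must have equal lengths")
    if frequencies is None:
        frequencies = [1] * len(haplotypes)
    if len(frequencies) != len(haplotypes):
        raise DataError("frequencies must parallel haplotypes")
    if ids is None:
        ids = [f"Hap_{i + 1}" for i in range(len(haplotypes))]

    full_len = L.pop()
    seg_cols = [
        j for j in range(full_len) if len({s[j] for s in haplotypes}) > 1
    ]
    cond = ["".join(s[j] for j in seg_cols) for s in haplotypes]

    n_obs = len(cond)
    seqs = list(cond)  # observed first, medians appended

    if n_obs > 1:
        while True:
            current_cost, _ = _mst(seqs)
            edges = _msn_edges(seqs, int(epsilon))
            adj: dict[int, set[int]] = {i: set() for i in range(len(seqs))}
            for i, j, _w in edges:
                adj[i].add(j)
                adj[j].add(i)
            candidates: set[str] = set()
            existing = set(seqs)
            for u in range(len(seqs)):
                neigh = sorted(adj[u])
                for ai in range(len(neigh)):
                    for bi in range(ai + 1, len(neigh)):
                        trio = sorted([u, neigh[ai], neigh[bi]])
                        m = _median(seqs[trio[0]], seqs[trio[1]], seqs[trio[2]])
                        if m not in existing:
                            candidates.add(m)
            best: tuple[int, str] | None = None
            for m in sorted(candidates):
                cost, _ = _mst(seqs + [m])
                if cost < current_cost and (best is None or (cost, m) < best):
                    best = (cost, m)
            if best is None:
                break
            seqs.append(best[1])

        # prune medians on no shortest connection between observed nodes
        changed = True
        while changed:
            changed = False
            edges = _msn_edges(seqs, int(epsilon))
            degree = {i: 0 for i in range(len(seqs))}
            for i, j, _w in edges:
                degree[i] += 1
                degree[j] += 1
            for idx in sorted(range(n_obs, len(seqs)), key=lambda i: seqs[i]):
                if degree.get(idx, 0) > 2:
                    continue
                m = seqs[idx]
                on_geodesic = any(
                    hamming(cond[a], m) + hamming(m, cond[b])
                    == hamming(cond[a], cond[b])
                    for a in range(n_obs)
                    for b in range(a + 1, n_obs)
                )
                if not on_geodesic:
                    seqs.pop(idx)
                    changed = True
                    break

    final_edges = _msn_edges(seqs, int(epsilon)) if len(seqs) > 1 else []

    nodes: list[NetworkNode] = []
    node_ids: list[str] = []
    med_no = 0
    for i, s in enumerate(seqs):
        if i < n_obs:
            nid = ids[i]
            traits = tuple(sorted((trait_table or {}).get(nid, {}).items()))
            nodes.append(NetworkNode(nid, s, "observed", frequencies[i], traits))
        else:
            med_no += 1
            nid = f"MV{med_no}"
            nodes.append(NetworkNode(nid, s, "median", 0))
        node_ids.append(nid)
    return HaplotypeNetwork(
        nodes=tuple(nodes),
        edges=tuple(
            (node_ids[i], node_ids[j], w) for i, j, w in final_edges
        ),
        epsilon=int(epsilon),
        segregating_columns=tuple(seg_cols),
    )


def spanning_cost(network: HaplotypeNetwork) -> int:
    """Minimum spanning cost over the network's node sequences."""
    cost, _ = _mst([n.sequence for n in network.nodes])
    return cost


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def export_network(network: HaplotypeNetwork, path, format: str = "graphml") -> None:
    """Write the network as GraphML, PopART-style NEXUS, or a TSV edge list."""
    path = str(path)
    if format == "graphml":
        nx.write_graphml(network.graph(), path)
    elif format == "nexus":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write(_to_nexus(network))
    elif format == "tsv":
        with open(path, "w", encoding="utf-8", newline="\n") as fh:
            fh.write("node_a\tnode_b\tmutations\n")
            for a, b, w in network.edges:
                fh.write(f"{a}\t{b}\t{w}\n")
    else:
        raise ConfigurationError(
            f"unknown network export format {format!r}; use graphml/nexus/tsv"
        )


def import_graphml(path) -> HaplotypeNetwork:
    """Re-read a GraphML export into an equivalent :class:`HaplotypeNetwork`."""
    g = nx.read_graphml(str(path))
    nodes = tuple(
        NetworkNode(
            node_id=str(nid),
            sequence=data["sequence"],
            kind=data["kind"],
            size=int(data["size"]),
            traits=tuple(sorted(json.loads(data.get("traits", "{}")).items())),
        )
        for nid, data in sorted(g.nodes(data=True))
    )
    edges = tuple(
        sorted((str(a), str(b), int(d["weight"])) for a, b, d in g.edges(data=True))
    )
    return HaplotypeNetwork(nodes=nodes, edges=edges, epsilon=0)


def _to_nexus(network: HaplotypeNetwork) -> str:
    taxa = [n.node_id for n in network.nodes if n.kind == "observed"]
    by_id = {n.node_id: n for n in network.nodes}
    lines = ["#NEXUS", ""]
    lines += [
        "BEGIN TAXA;",
        f"    DIMENSIONS NTAX={len(taxa)};",
        "    TAXLABELS " + " ".join(taxa) + ";",
        "END;",
        "",
    ]
    nchar = len(network.nodes[0].sequence) if network.nodes else 0
    if nchar:
        lines += [
            "BEGIN CHARACTERS;",
            f"    DIMENSIONS NCHAR={nchar};",
            "    FORMAT DATATYPE=DNA MISSING=? GAP=-;",
            "    MATRIX",
        ]
        for t in taxa:
            lines.append(f"        {t} {by_id[t].sequence}")
        lines += ["    ;", "END;", ""]
    trait_labels = sorted({g for t in taxa for g, _ in by_id[t].traits})
    if trait_labels:
        lines += [
            "BEGIN TRAITS;",
            f"    Dimensions NTRAITS={len(trait_labels)};",
            "    Format labels=yes missing=? separator=Comma;",
            "    TraitLabels " + " ".join(trait_labels) + ";",
            "    Matrix",
        ]
        for t in taxa:
            comp = dict(by_id[t].traits)
            row = ",".join(str(comp.get(g, 0)) for g in trait_labels)
            lines.append(f"        {t} {row}")
        lines += ["    ;", "END;", ""]
    return "\n".join(lines) + "\n"


def edge_cut_groups(network: HaplotypeNetwork, max_weight: int = 1) -> list[set[str]]:
    """Connected components after removing edges heavier than ``max_weight``.

    A convenience grouping only — published network figures often carry
    hand-drawn group outlines, which this does not reproduce.
    """
    g = network.graph()
    g.remove_edges_from(
        [(a, b) for a, b, d in g.edges(data=True) if d["weight"] > max_weight]
    )
    return [set(c) for c in nx.connected_components(g)]
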