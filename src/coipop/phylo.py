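"""TN93 distances and neighbor-joining trees.

A distance-based summary used to check that haplogroups form coherent
clusters: pairwise Tamura–Nei (1993) distances (two transition classes,
unequal base frequencies, no rate heterogeneity) and the Saitou–Nei
neighbor-joining tree with Newick output.  This is deliberately not a
maximum-likelihood inference engine; it exists for cluster sanity
checks, not for publishable phylogenies.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field

import numpy as np

from .errors import DataError
from .iupac import UNAMBIGUOUS

logger = logging.getLogger(__name__)

__all__ = [
    "DistanceMatrix",
    "TreeNode",
    "tn93_distance",
    "tn93_matrix",
    "nj_tree",
    "write_newick",
]


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise DataError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise DataError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise DataError("distance matrix diagonal must be exactly 0")
        object.__setattr__(self, "values", v)


@dataclass
class TreeNode:
    """A rooted representation of an (unrooted) tree.

    ``children`` pairs each child with the length of the branch leading to
    it; a node is a leaf iff it has no children.
    """

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [lf for child, _ in self.children for lf in child.leaves()]

    def leaf_path_lengths(self) -> dict[tuple[str, str], float]:
        """Sum of branch lengths between every pair of leaf labels."""
        dists: dict[tuple[str, str], float] = {}

        def down(node: TreeNode) -> list[tuple[str, float]]:
            if node.is_leaf:
                return [(node.label or "", 0.0)]
            bundles = []
            for child, blen in node.children:
                sub = [(lab, d + blen) for lab, d in down(child)]
                bundles.append(sub)
            for i in range(len(bundles)):
                for j in range(i + 1, len(bundles)):
                    for la, da in bundles[i]:
                        for lb, db in bundles[j]:
                            key = tuple(sorted((la, lb)))
                            dists[key] = da + db
            return [pair for sub in bundles for pair in sub]

        down(self)
        return dists


def _pair_columns(a: str, b: str) -> list[int]:
    return [
        j for j in range(len(a)) if a[j] in UNAMBIGUOUS and b[j] in UNAMBIGUOUS
    ]


PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}


def tn93_distance(seq_a: str, seq_b: str,
                  comparison_policy: str = "pairwise_deletion") -> float:
    """Tamura–Nei (1993) distance between two aligned sequences.

    Base frequencies are estimated from the pooled pair over the usable
    columns; A<->G and C<->T transitions form separate classes.  Returns
    ``nan`` (with a logged warning) when a logarithm argument is
    non-positive, i.e. the pair is saturated under the model.
    """
    a, b = seq_a.upper(), seq_b.upper()
    if len(a) != len(b):
        raise DataError("TN93 distance requires equal-length sequences")
    cols = _pair_columns(a, b)
    if not cols:
        raise DataError("TN93 distance: no usable columns")
    L = len(cols)
    counts = {x: 0 for x in "ACGT"}
    p1 = p2 = q = 0
    for j in cols:
        counts[a[j]] += 1
        counts[b[j]] += 1
        if a[j] != b[j]:
            pair = {a[j], b[j]}
            if pair == {"A", "G"}:
                p1 += 1
            elif pair == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    if p1 == p2 == q == 0:
        return 0.0
    tot = 2 * L
    gA, gC, gG, gT = (counts[x] / tot for x in "ACGT")
    gR, gY = gA + gG, gC + gT
    P1, P2, Q = p1 / L, p2 / L, q / L

    k1 = 2 * gA * gG / gR if gR > 0 else 0.0
    k2 = 2 * gT * gC / gY if gY > 0 else 0.0
    k3 = 2 * (gR * gY - (gA * gG * gY / gR if gR > 0 else 0.0)
              - (gT * gC * gR / gY if gY > 0 else 0.0))

    d = 0.0
    for k, P, g in ((k1, P1, gR), (k2, P2, gY)):
        if k == 0:
            if P > 0:
                logger.warning("TN93: transition observed in a zero-frequency class; saturated")
                return math.nan
            continue
        w = 1 - P / k - Q / (2 * g)
        if w <= 0:
            logger.warning("TN93: saturated pair (log argument <= 0)")
            return math.nan
        d += -k * math.log(w)
    if k3 > 0:
        w3 = 1 - Q / (2 * gR * gY)
        if w3 <= 0:
            logger.warning("TN93: saturated pair (transversion term)")
            return math.nan
        d += -k3 * math.log(w3)
    elif Q > 0:
        return math.nan
    return d


def tn93_matrix(labels: list[str], seqs: list[str],
                comparison_policy: str = "pairwise_deletion") -> DistanceMatrix:
    n = len(labels)
    if n != len(seqs):
        raise DataError("labels and sequences must parallel")
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = tn93_distance(seqs[i], seqs[j], comparison_policy)
            if math.isnan(d):
                raise DataError(
                    f"TN93 distance saturated for pair ({labels[i]}, {labels[j]})"
                )
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels=tuple(labels), values=values)


def nj_tree(matrix: DistanceMatrix) -> TreeNode:
    """Saitou–Nei neighbor-joining with a trifurcating root.

    Ties in the Q criterion break by label order; negative branch lengths
    are clamped to zero with a logged note.  On an all-zero matrix the
    result is a star tree (zero-length branches, label order).
    """
    labels = list(matrix.labels)
    n = len(labels)
    if n < 3:
        raise DataError("neighbor-joining requires at least 3 taxa")
    D = {la: {lb: float(matrix.values[i, j]) for j, lb in enumerate(labels)}
         for i, la in enumerate(labels)}
    if all(matrix.values[i, j] == 0 for i in range(n) for j in range(n)):
        return TreeNode(children=[(TreeNode(label=l), 0.0) for l in sorted(labels)])

    nodes: dict[str, TreeNode] = {l: TreeNode(label=l) for l in labels}
    active = sorted(labels)
    clamped = 0
    join_no = 0
    while len(active) > 3:
        N = len(active)
        r = {u: sum(D[u][v] for v in active if v != u) for u in active}
        best = None
        for i in range(N):
            for j in range(i + 1, N):
                u, v = active[i], active[j]
                qq = (N - 2) * D[u][v] - r[u] - r[v]
                key = (qq, u, v)
                if best is None or key < best:
                    best = key
        _, u, v = best
        bu = 0.5 * D[u][v] + (r[u] - r[v]) / (2 * (N - 2))
        bv = D[u][v] - bu
        if bu < 0 or bv < 0:
            clamped += 1
            bu, bv = max(bu, 0.0), max(bv, 0.0)
        join_no += 1
        new_label = f"_nj{join_no}"
        nodes[new_label] = TreeNode(children=[(nodes[u], bu), (nodes[v], bv)])
        D[new_label] = {}
        for w in active:
            if w in (u, v):
                continue
            d = 0.5 * (D[u][w] + D[v][w] - D[u][v])
            D[new_label][w] = D[w][new_label] = d
        D[new_label][new_label] = 0.0
        active = sorted(w for w in active if w not in (u, v)) + [new_label]
        active.sort()
    u, v, w = active
    bu = 0.5 * (D[u][v] + D[u][w] - D[v][w])
    bv = 0.5 * (D[u][v] + D[v][w] - D[u][w])
    bw = 0.5 * (D[u][w] + D[v][w] - D[u][v])
    lens = [bu, bv, bw]
    if any(x < 0 for x in lens):
        clamped += 1
        lens = [max(x, 0.0) for x in lens]
    if clamped:
        logger.info("neighbor-joining: %d negative branch length(s) clamped to 0",
                    clamped)
    return TreeNode(children=[(nodes[u], lens[0]), (nodes[v], lens[1]),
                              (nodes[w], lens[2])])


_SAFE_LABEL = re.compile(r"^[A-Za-z0-9_.|-]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def write_newick(tree: TreeNode) -> str:
    """Serialize a tree as a Newick string with branch lengths."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf:
            return _quote(node.label or "")
        inner = ",".join(
            f"{fmt(child)}:{blen:.10g}" for child, blen in node.children
        )
        name = _quote(node.label) if node.label else ""
        return f"({inner}){name}"

    return fmt(tree) + ";"
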