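"""Independent oracle implementations used only by the tests.

Each oracle recomputes a quantity by a different route than the package
(exhaustive enumeration, exact rational arithmetic, brute-force search)
so agreement is evidence of correctness rather than repetition.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

# IUPAC base sets, restated here so the oracles do not share package tables
SETS = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def expand(pattern: str) -> list[str]:
    """All concrete ACGT strings an IUPAC pattern denotes."""
    return ["".join(p) for p in itertools.product(*(SETS[c] for c in pattern))]


def digest_cuts_by_expansion(seq: str, recognition: str, cut_offset: int) -> list[int]:
    """Cut prefix-lengths by exhaustively matching every expansion at every offset."""
    words = set(expand(recognition))
    k = len(recognition)
    cuts = set()
    for start in range(len(seq) - k + 1):
        if seq[start : start + k] in words:
            pos = start + cut_offset
            if 0 < pos < len(seq):
                cuts.add(pos)
    return sorted(cuts)


def primer_hits_brute(seq: str, primer: str, max_mismatch: int) -> list[tuple[str, int, int]]:
    """Sliding-window scan over every offset and both strands."""
    comp = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")
    rc = primer.translate(comp)[::-1]
    out = []
    for strand, query in (("+", primer), ("-", rc)):
        for start in range(len(seq) - len(query) + 1):
            mism = 0
            for w, q in zip(seq[start : start + len(query)], query):
                if not set(SETS[w]) & set(SETS[q]):
                    mism += 1
            if mism <= max_mismatch:
                out.append((strand, start, mism))
    return sorted(out, key=lambda h: (h[1], h[0]))


def hd_exact(frequencies) -> Fraction:
    """Nei's unbiased haplotype diversity as an exact fraction."""
    n = sum(frequencies)
    return Fraction(n, n - 1) * (1 - sum(Fraction(f, n) ** 2 for f in frequencies))


def tajima_d_exact(seqs: list[str]) -> float:
    """Tajima's D with every intermediate as an exact fraction.

    Columns are used only if all sequences carry A/C/G/T there
    (complete deletion).
    """
    n = len(seqs)
    cols = [j for j in range(len(seqs[0]))
            if all(s[j] in "ACGT" for s in seqs)]
    S = sum(1 for j in cols if len({s[j] for s in seqs}) > 1)
    if S == 0:
        raise ValueError("D undefined for S = 0")
    diffs = sum(
        sum(a[j] != b[j] for j in cols)
        for a, b in itertools.combinations(seqs, 2)
    )
    theta_pi = Fraction(diffs, n * (n - 1) // 2)
    a1 = sum(Fraction(1, i) for i in range(1, n))
    a2 = sum(Fraction(1, i * i) for i in range(1, n))
    b1 = Fraction(n + 1, 3 * (n - 1))
    b2 = Fraction(2 * (n * n + n + 3), 9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - Fraction(n + 2, n) / a1 + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    return float(theta_pi - S / a1) / math.sqrt(var)


def stirling_by_polynomial(n: int) -> list[int]:
    """|s(n, k)| as coefficients of the rising factorial x(x+1)...(x+n-1).

    A genuinely different route than the package's triangular recurrence.
    """
    coeffs = [1]  # polynomial "1"
    for i in range(n):
        # multiply by (x + i)
        new = [0] * (len(coeffs) + 1)
        for k, c in enumerate(coeffs):
            new[k] += c * i
            new[k + 1] += c
        coeffs = new
    return coeffs  # coeffs[k] = |s(n, k)|


def ewens_exact(n: int, theta: Fraction) -> list[Fraction]:
    """Pr(K = k), k = 1..n, as exact fractions for rational theta."""
    s = stirling_by_polynomial(n)
    rising = Fraction(1)
    for i in range(n):
        rising *= theta + i
    return [s[k] * theta**k / rising for k in range(1, n + 1)]


def fs_exact(seqs: list[str]) -> float:
    """Fu's Fs via exact-fraction theta_pi and Ewens probabilities."""
    n = len(seqs)
    cols = [j for j in range(len(seqs[0]))
            if all(s[j] in "ACGT" for s in seqs)]
    diffs = sum(
        sum(a[j] != b[j] for j in cols)
        for a, b in itertools.combinations(seqs, 2)
    )
    theta_pi = Fraction(diffs, n * (n - 1) // 2)
    k_obs = len({tuple(s[j] for j in cols) for s in seqs})
    if theta_pi == 0 or k_obs == 1:
        raise ValueError("Fs undefined without variation")
    probs = ewens_exact(n, theta_pi)
    s_prime = sum(probs[k_obs - 1:])
    return math.log(float(s_prime) / float(1 - s_prime))


def mst_cost(seqs: list[str]) -> int:
    """Prim's algorithm on Hamming distances (package uses Kruskal)."""
    n = len(seqs)
    if n == 0:
        return 0
    dist = lambda a, b: sum(x != y for x, y in zip(a, b))
    in_tree = {0}
    cost = 0
    while len(in_tree) < n:
        best = min(
            (dist(seqs[i], seqs[j]), j)
            for i in in_tree for j in range(n) if j not in in_tree
        )
        cost += best[0]
        in_tree.add(best[1])
    return cost


def steiner_optimum(observed: list[str], max_extra: int | None = None) -> int:
    """Minimum spanning cost over observed nodes plus any Steiner points.

    Steiner candidates are all sequences over the per-column observed
    state sets; at most ``len(observed) - 2`` extra points are ever needed.
    Exhaustive, so only usable for <= 4 haplotypes over <= 5 columns.
    """
    t = len(observed)
    if max_extra is None:
        max_extra = max(t - 2, 0)
    state_sets = [sorted(set(col)) for col in zip(*observed)]
    candidates = ["".join(p) for p in itertools.product(*state_sets)]
    candidates = [c for c in candidates if c not in set(observed)]
    best = mst_cost(observed)
    for r in range(1, max_extra + 1):
        for extra in itertools.combinations(candidates, r):
            best = min(best, mst_cost(observed + list(extra)))
    return best
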