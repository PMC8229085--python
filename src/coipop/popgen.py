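"""Haplotype-level population-genetics statistics from first principles.

Implements the DnaSP-style summary used for intraspecific mtDNA surveys:
haplotype collapsing, Nei's haplotype diversity with its sampling
variance, per-site nucleotide diversity, Watterson's theta, Tajima's D,
and Fu's Fs via the Ewens sampling formula with exact big-integer
Stirling numbers of the first kind.

Column handling is explicit: under the default ``complete_deletion``
policy a column is used only if every sequence carries an unambiguous
base there (gaps and IUPAC ambiguity codes exclude the column), matching
the common DnaSP default.  ``pairwise_deletion`` evaluates each pair of
sequences over the columns where both are unambiguous.

Statistics that are undefined on degenerate input (no segregating sites,
a single haplotype) are reported as ``None`` together with the reason,
never silently as zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .errors import DataError
from .iupac import UNAMBIGUOUS
from .seqio import SpecimenRecord

POLICIES = ("complete_deletion", "pairwise_deletion")


# ---------------------------------------------------------------------------
# input normalisation
# ---------------------------------------------------------------------------

def _as_pairs(records) -> list[tuple[str, str]]:
    pairs = []
    for r in records:
        if isinstance(r, SpecimenRecord):
            pairs.append((r.specimen_id, r.sequence.upper()))
        else:
            name, seq = r
            pairs.append((name, seq.upper()))
    if not pairs:
        raise DataError("no sequences provided")
    lengths = {len(s) for _, s in pairs}
    if len(lengths) > 1:
        raise DataError(
            f"sequences have unequal lengths {sorted(lengths)}; align them first"
        )
    return pairs


def used_columns(seqs: list[str], policy: str = "complete_deletion") -> list[int]:
    """Column indices usable under the comparison policy.

    For ``complete_deletion`` these are the columns where every sequence has
    an unambiguous base; ``pairwise_deletion`` has no global column set and
    returns all columns (pairs restrict further).
    """
    if policy not in POLICIES:
        raise DataError(f"unknown comparison policy {policy!r}")
    L = len(seqs[0])
    if policy == "pairwise_deletion":
        return list(range(L))
    return [
        j for j in range(L) if all(s[j] in UNAMBIGUOUS for s in seqs)
    ]


def _pair_diff(a: str, b: str, cols: list[int], policy: str) -> tuple[int, int]:
    """(differences, compared sites) for one pair under the policy."""
    if policy == "complete_deletion":
        d = sum(a[j] != b[j] for j in cols)
        return d, len(cols)
    d = used = 0
    for j in cols:
        if a[j] in UNAMBIGUOUS and b[j] in UNAMBIGUOUS:
            used += 1
            if a[j] != b[j]:
                d += 1
    return d, used


# ---------------------------------------------------------------------------
# haplotype collapsing
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HaplotypeTable:
    haplotypes: tuple[tuple[str, str, tuple[str, ...]], ...]  # (id, seq, members)
    n: int
    h: int
    frequencies: tuple[int, ...]

    def member_map(self) -> dict[str, str]:
        """specimen_id -> haplotype_id"""
        return {
            m: hap_id for hap_id, _, members in self.haplotypes for m in members
        }


def collapse_haplotypes(records, comparison_policy: str = "complete_deletion") -> HaplotypeTable:
    """Group identical sequences (over used columns) into haplotypes.

    Haplotypes are numbered ``Hap_1`` ... in order of first occurrence; the
    representative sequence is the first member's full sequence.
    """
    pairs = _as_pairs(records)
    seqs = [s for _, s in pairs]
    cols = used_columns(seqs, comparison_policy)
    groups: list[tuple[str, str, list[str]]] = []  # (key/repr-used, full seq, members)
    for name, seq in pairs:
        key = "".join(seq[j] for j in cols)
        for i, (gkey, _, members) in enumerate(groups):
            if comparison_policy == "complete_deletion":
                same = key == gkey
            else:
                same = _pair_diff(seq, groups[i][1], cols, comparison_policy)[0] == 0
            if same:
                members.append(name)
                break
        else:
            groups.append((key, seq, [name]))
    haplotypes = tuple(
        (f"Hap_{i + 1}", seq, tuple(members))
        for i, (_, seq, members) in enumerate(groups)
    )
    return HaplotypeTable(
        haplotypes=haplotypes,
        n=len(pairs),
        h=len(haplotypes),
        frequencies=tuple(len(members) for _, _, members in haplotypes),
    )


# ---------------------------------------------------------------------------
# diversity statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DiversityStats:
    n: int
    h: int
    Hd: float
    Hd_sd: float
    pi: float | None
    pi_sd: float | None
    S: int
    sites_used: int
    notes: tuple[str, ...] = ()


@dataclass(frozen=True)
class NeutralityStats:
    n: int
    S: int
    tajima_d: float | None
    fu_fs: float | None
    theta_pi: float  # mean pairwise differences per sequence
    theta_w: float  # Watterson's estimator, per sequence
    k_obs: int
    s_prime: float | None  # Pr(K >= k_obs) under Ewens at theta_pi
    notes: tuple[str, ...] = ()


def haplotype_diversity(table: HaplotypeTable) -> tuple[float, float]:
    """Nei's unbiased haplotype diversity and its standard deviation.

    Hd = n/(n-1) (1 - sum p_i^2); the variance is Nei's (1987) sampling
    variance
    V = 2/(n(n-1)) { 2(n-2) [sum p^3 - (sum p^2)^2] + sum p^2 - (sum p^2)^2 }.
    """
    n = table.n
    if n < 2:
        raise DataError("haplotype diversity undefined for n < 2")
    p = np.asarray(table.frequencies, dtype=float) / n
    sum_p2 = float(np.sum(p**2))
    sum_p3 = float(np.sum(p**3))
    hd = n / (n - 1) * (1.0 - sum_p2)
    var = (2.0 / (n * (n - 1))) * (
        2.0 * (n - 2) * (sum_p3 - sum_p2**2) + sum_p2 - sum_p2**2
    )
    return hd, math.sqrt(max(var, 0.0))


def _pairwise_totals(pairs, policy):
    """Sum of pairwise differences and per-pair per-site mean."""
    seqs = [s for _, s in pairs]
    cols = used_columns(seqs, policy)
    n = len(seqs)
    total_d = 0
    per_site = []
    for i in range(n):
        for j in range(i + 1, n):
            d, used = _pair_diff(seqs[i], seqs[j], cols, policy)
            total_d += d
            if used:
                per_site.append(d / used)
    sites = len(cols) if policy == "complete_deletion" else len(seqs[0])
    return total_d, per_site, sites


def nucleotide_diversity(
    records, comparison_policy: str = "complete_deletion"
) -> tuple[float | None, float | None, int]:
    """Per-site nucleotide diversity pi, its SD, and the sites used.

    pi is the mean proportion of differing used sites over all sequence
    pairs.  The SD is the square root of the standard no-recombination
    sampling variance (Nei 1987, eq. 10.7):
    V(pi) = (n+1) pi / (3 (n-1) L) + 2 (n^2 + n + 3) pi^2 / (9 n (n-1)).
    """
    pairs = _as_pairs(records)
    n = len(pairs)
    if n < 2:
        raise DataError("nucleotide diversity undefined for n < 2")
    total_d, per_site, sites = _pairwise_totals(pairs, comparison_policy)
    if comparison_policy == "complete_deletion":
        if sites == 0:
            return None, None, 0
        pi = total_d / (n * (n - 1) / 2) / sites
        L = sites
    else:
        if not per_site:
            return None, None, 0
        pi = float(np.mean(per_site))
        L = sites
    var = (n + 1) * pi / (3 * (n - 1) * L) + (
        2 * (n**2 + n + 3) * pi**2 / (9 * n * (n - 1))
    )
    return pi, math.sqrt(max(var, 0.0)), L


def segregating_sites(records, comparison_policy: str = "complete_deletion") -> tuple[int, int]:
    """(S, sites_used): polymorphic used columns."""
    pairs = _as_pairs(records)
    seqs = [s for _, s in pairs]
    cols = used_columns(seqs, comparison_policy)
    if comparison_policy == "pairwise_deletion":
        # a column segregates if it carries >= 2 distinct unambiguous bases
        S = 0
        for j in cols:
            states = {s[j] for s in seqs if s[j] in UNAMBIGUOUS}
            if len(states) > 1:
                S += 1
        return S, len(cols)
    S = sum(1 for j in cols if len({s[j] for s in seqs}) > 1)
    return S, len(cols)


def mean_pairwise_differences(records, comparison_policy: str = "complete_deletion") -> float:
    """theta_pi: mean number of pairwise differences per sequence (not per site)."""
    pairs = _as_pairs(records)
    n = len(pairs)
    if n < 2:
        raise DataError("pairwise differences undefined for n < 2")
    total_d, per_site, sites = _pairwise_totals(pairs, comparison_policy)
    if comparison_policy == "pairwise_deletion" and per_site:
        # rescale per-pair per-site means to the full column count
        return float(np.mean(per_site)) * sites
    return total_d / (n * (n - 1) / 2)


def diversity_stats(records, comparison_policy: str = "complete_deletion") -> DiversityStats:
    """Full DnaSP-style diversity summary for one population."""
    table = collapse_haplotypes(records, comparison_policy)
    notes: list[str] = []
    hd, hd_sd = haplotype_diversity(table)
    pi, pi_sd, sites = nucleotide_diversity(records, comparison_policy)
    if pi is None:
        notes.append("pi undefined: no usable sites")
    S, _ = segregating_sites(records, comparison_policy)
    return DiversityStats(
        n=table.n, h=table.h, Hd=hd, Hd_sd=hd_sd, pi=pi, pi_sd=pi_sd,
        S=S, sites_used=sites, notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Tajima's D
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return dict(a1=a1, a2=a2, b1=b1, b2=b2, c1=c1, c2=c2, e1=e1, e2=e2)


def tajimas_d(records, comparison_policy: str = "complete_deletion") -> NeutralityStats:
    """Tajima's D = (theta_pi - S/a1) / sqrt(e1 S + e2 S (S-1)).

    Undefined (``None``) when S = 0; never reported as 0 in that case.
    """
    pairs = _as_pairs(records)
    n = len(pairs)
    if n < 2:
        raise DataError("Tajima's D undefined for n < 2")
    S, _ = segregating_sites(records, comparison_policy)
    theta_pi = mean_pairwise_differences(records, comparison_policy)
    table = collapse_haplotypes(records, comparison_policy)
    consts = tajima_constants(n)
    theta_w = S / consts["a1"]
    notes: list[str] = []
    if S == 0:
        d = None
        notes.append("Tajima's D undefined: no segregating sites")
    else:
        var = consts["e1"] * S + consts["e2"] * S * (S - 1)
        d = (theta_pi - theta_w) / math.sqrt(var)
    return NeutralityStats(
        n=n, S=S, tajima_d=d, fu_fs=None, theta_pi=theta_pi, theta_w=theta_w,
        k_obs=table.h, s_prime=None, notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Ewens sampling formula and Fu's Fs
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def stirling_first_row(n: int) -> tuple[int, ...]:
    """Unsigned Stirling numbers of the first kind |s(n, k)| for k = 0..n.

    Exact integers by the recurrence |s(n+1,k)| = n |s(n,k)| + |s(n,k-1)|.
    """
    row = (1,)  # n = 0
    for m in range(n):
        prev = row
        row = tuple(
            (m * prev[k] if k <= m else 0) + (prev[k - 1] if k >= 1 else 0)
            for k in range(m + 2)
        )
    return row


def ewens_k_distribution(n: int, theta: float) -> np.ndarray:
    """Pr(K = k) for k = 1..n under the Ewens sampling formula.

    Pr(K=k) = |s(n,k)| theta^k / prod_{i=0}^{n-1} (theta + i), evaluated in
    log space (math.log handles the exact big-integer Stirling numbers).
    """
    if n < 1:
        raise DataError("n must be >= 1")
    if theta <= 0:
        raise DataError("theta must be > 0")
    row = stirling_first_row(n)
    log_rising = sum(math.log(theta + i) for i in range(n))
    log_theta = math.log(theta)
    logs = np.array(
        [math.log(row[k]) + k * log_theta - log_rising for k in range(1, n + 1)]
    )
    return np.exp(logs)


def fus_fs(records, comparison_policy: str = "complete_deletion") -> NeutralityStats:
    """Fu's (1997) Fs statistic.

    With theta taken as the mean number of pairwise differences per sequence
    (theta_pi), S' = Pr(K >= k_obs) under the Ewens sampling formula and
    Fs = ln(S' / (1 - S')).  Undefined when there is no variation or when
    every sequence is its own haplotype *and* theta_pi = 0.
    """
    pairs = _as_pairs(records)
    n = len(pairs)
    if n < 2:
        raise DataError("Fu's Fs undefined for n < 2")
    theta_pi = mean_pairwise_differences(records, comparison_policy)
    table = collapse_haplotypes(records, comparison_policy)
    k_obs = table.h
    S, _ = segregating_sites(records, comparison_policy)
    consts = tajima_constants(n)
    notes: list[str] = []
    if theta_pi <= 0 or k_obs == 1:
        return NeutralityStats(
            n=n, S=S, tajima_d=None, fu_fs=None, theta_pi=theta_pi,
            theta_w=S / consts["a1"], k_obs=k_obs, s_prime=None,
            notes=("Fu's Fs undefined: no sequence variation",),
        )
    probs = ewens_k_distribution(n, theta_pi)
    s_prime = float(probs[k_obs - 1 :].sum())
    if not 0.0 < s_prime < 1.0:
        return NeutralityStats(
            n=n, S=S, tajima_d=None, fu_fs=None, theta_pi=theta_pi,
            theta_w=S / consts["a1"], k_obs=k_obs, s_prime=s_prime,
            notes=("Fu's Fs undefined: S' at the boundary of (0, 1)",),
        )
    fs = math.log(s_prime / (1.0 - s_prime))
    return NeutralityStats(
        n=n, S=S, tajima_d=None, fu_fs=fs, theta_pi=theta_pi,
        theta_w=S / consts["a1"], k_obs=k_obs, s_prime=s_prime, notes=tuple(notes),
    )


def neutrality_stats(records, comparison_policy: str = "complete_deletion") -> NeutralityStats:
    """Combined Tajima's D + Fu's Fs summary."""
    d = tajimas_d(records, comparison_policy)
    f = fus_fs(records, comparison_policy)
    return NeutralityStats(
        n=d.n, S=d.S, tajima_d=d.tajima_d, fu_fs=f.fu_fs, theta_pi=d.theta_pi,
        theta_w=d.theta_w, k_obs=f.k_obs, s_prime=f.s_prime,
        notes=tuple(d.notes + f.notes),
    )
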