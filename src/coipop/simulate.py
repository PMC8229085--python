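"""Synthetic COI-like specimen populations with controlled structure.

The generator builds an amplicon *template* per haplogroup whose ApoI
sites induce exactly a requested set of diagnostic cut positions, then
derives haplotypes from the template by point substitutions placed
outside the recognition sites, so every simulated specimen carries its
haplogroup's RFLP pattern by construction.  Haplotype frequencies and
per-haplotype mutation counts are chosen to hit target haplotype
diversity (Hd) and per-site nucleotide diversity (pi), which makes the
downstream statistics of a simulated dataset analytically predictable:
with private mutations at distinct positions, the distance between two
haplotypes is the sum of their mutation counts, so pi depends only on
the frequency vector and the mutation-count vector.

Two presets emulate the survey structure reported for Italian MED
whiteflies: a MEDQ1-like population (n=31, 13 haplotypes, Hd ~ 0.908,
pi ~ 0.004/site, star-like genealogy) and a MEDQ2-like population
(n=23, 3 haplotypes with frequencies 19/3/1, Hd ~ 0.312, pi ~ 0.0004).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np

from .errors import GenerationError
from .iupac import IUPAC_SETS, UNAMBIGUOUS
from .rflp import APOI, EnzymeSpec, digest
from .seqio import SpecimenRecord

BASES = "ACGT"


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters for one synthetic haplogroup population."""

    label: str
    cut_positions: tuple[int, ...]
    n_specimens: int
    n_haplotypes: int
    seed: int = 0
    amplicon_length: int = 866
    #: explicit counts per haplotype, or "auto" to solve for target_hd
    haplotype_frequencies: tuple[int, ...] | str = "auto"
    #: per-haplotype substitution counts (first haplotype is the template and
    #: always gets 0), an int applied to every derived haplotype, or "auto"
    #: to solve for target_pi
    mutations_per_haplotype: tuple[int, ...] | int | str = "auto"
    target_hd: float = 0.9
    target_pi: float = 0.004
    flank_lengths: tuple[int, int] = (100, 100)
    primer_length: int = 20
    allow_site_mutations: bool = False
    region: str = "SimRegion"
    locality: str = "SimLocality"
    host_plant: str = "Solanum lycopersicum"
    setting: str = "open_field"
    year: int = 2018

    def __post_init__(self) -> None:
        # coerce list-valued config (e.g. from YAML) to tuples
        for name in ("cut_positions", "haplotype_frequencies",
                     "mutations_per_haplotype", "flank_lengths"):
            val = getattr(self, name)
            if isinstance(val, list):
                object.__setattr__(self, name, tuple(val))
        if self.n_haplotypes > self.n_specimens:
            raise GenerationError("n_haplotypes must not exceed n_specimens")
        if self.n_haplotypes < 1 or self.n_specimens < 1:
            raise GenerationError("need at least one haplotype and one specimen")
        if isinstance(self.haplotype_frequencies, tuple):
            f = self.haplotype_frequencies
            if len(f) != self.n_haplotypes or any(x < 1 for x in f):
                raise GenerationError("frequency vector must have n_haplotypes positive parts")
            if sum(f) != self.n_specimens:
                raise GenerationError("haplotype_frequencies must sum to n_specimens")
        for p in self.cut_positions:
            if not 0 < p < self.amplicon_length:
                raise GenerationError(
                    f"cut position {p} outside (0, {self.amplicon_length})"
                )


@dataclass(frozen=True)
class SyntheticPopulation:
    """A generated population plus the ground truth it was built from."""

    config: GeneratorConfig
    template: str
    haplotype_sequences: tuple[str, ...]  # amplicon-only, template first
    frequencies: tuple[int, ...]
    mutation_counts: tuple[int, ...]
    records: tuple[SpecimenRecord, ...]  # full sequences (with flanks)
    fwd_primer: str
    rev_primer: str
    assignments: tuple[int, ...]  # specimen -> haplotype index

    @property
    def expected_hd(self) -> float:
        return float(nei_hd(self.frequencies))

    @property
    def expected_pi(self) -> float:
        return expected_pi(self.frequencies, self.mutation_counts,
                           self.config.amplicon_length)


def nei_hd(frequencies) -> Fraction:
    """Nei's unbiased haplotype diversity, exactly, from counts."""
    n = sum(frequencies)
    if n < 2:
        return Fraction(0)
    sum_p2 = sum(Fraction(f, n) ** 2 for f in frequencies)
    return Fraction(n, n - 1) * (1 - sum_p2)


def expected_pi(frequencies, mutation_counts, amplicon_length: int) -> float:
    """Exact per-site pi when each haplotype's mutations are private.

    d(i, j) = m_i + m_j, hence
    pi = sum_i m_i f_i (n - f_i) / (C(n, 2) * L).
    """
    n = sum(frequencies)
    if n < 2:
        return 0.0
    num = sum(m * f * (n - f) for m, f in zip(mutation_counts, frequencies))
    return num / (n * (n - 1) / 2) / amplicon_length


def _compositions(n: int, h: int):
    """All descending h-part compositions (partitions) of n."""

    def parts(n, h, maxpart):
        if h == 1:
            if n <= maxpart:
                yield (n,)
            return
        for first in range(min(n - h + 1, maxpart), (n + h - 1) // h - 1, -1):
            for rest in parts(n - first, h - 1, first):
                yield (first, *rest)

    yield from parts(n, h, n)


def frequencies_for_target_hd(
    n: int, h: int, target_hd: float
) -> tuple[tuple[int, ...], float]:
    """Frequency vector of h haplotypes among n specimens closest to a target Hd.

    Exhaustive over all partitions for small n (<= 60); hill-climbing from the
    most even split otherwise.  Returns the composition (descending counts)
    and the exactly achieved Hd.  An unreachable target returns the nearest
    achievable composition rather than failing.
    """
    if not 0 <= target_hd <= 1:
        raise GenerationError("target_hd must be in [0, 1]")
    if h > n:
        raise GenerationError("h must not exceed n")
    if h == 1:
        return (n,), 0.0
    if n <= 60:
        best = min(
            _compositions(n, h),
            key=lambda c: (abs(float(nei_hd(c)) - target_hd), c),
        )
        return best, float(nei_hd(best))
    # greedy hill climb for large n
    base, extra = divmod(n, h)
    comp = [base + 1] * extra + [base] * (h - extra)
    err = abs(float(nei_hd(comp)) - target_hd)
    while True:
        best_move, best_err = None, err
        for i, j in itertools.permutations(range(h), 2):
            if comp[j] <= 1:
                continue
            comp[i] += 1
            comp[j] -= 1
            e = abs(float(nei_hd(comp)) - target_hd)
            if e < best_err - 1e-15:
                best_move, best_err = (i, j), e
            comp[i] -= 1
            comp[j] += 1
        if best_move is None:
            break
        i, j = best_move
        comp[i] += 1
        comp[j] -= 1
        err = best_err
    comp.sort(reverse=True)
    return tuple(comp), float(nei_hd(comp))


def mutations_for_target_pi(
    frequencies: tuple[int, ...], amplicon_length: int, target_pi: float
) -> tuple[int, ...]:
    """Integer per-haplotype mutation counts whose implied pi is nearest target.

    The first haplotype is the central (template) haplotype with 0 mutations;
    every other haplotype gets >= 1 so all are distinct.
    """
    h = len(frequencies)
    counts = [0] + [1] * (h - 1)
    if h == 1:
        return tuple(counts)

    def err(c):
        return abs(expected_pi(frequencies, c, amplicon_length) - target_pi)

    # round-robin increments keep the mutation load even across haplotypes,
    # preserving the star-like shape of the genealogy
    while True:
        current = err(counts)
        order = sorted(range(1, h), key=lambda i: (counts[i], i))
        for i in order:
            counts[i] += 1
            if err(counts) < current - 1e-15:
                break
            counts[i] -= 1
        else:
            break
    return tuple(counts)


def _site_footprints(cut_positions, enzyme: EnzymeSpec) -> set[int]:
    occupied: set[int] = set()
    k = len(enzyme.recognition)
    for p in cut_positions:
        start = p - enzyme.cut_offset
        occupied.update(range(start, start + k))
    return occupied


def _validate_cuts(cuts, amplicon_length: int, enzyme: EnzymeSpec) -> None:
    k = len(enzyme.recognition)
    for p in cuts:
        if not 0 < p < amplicon_length:
            raise GenerationError(f"cut position {p} outside (0, {amplicon_length})")
        start = p - enzyme.cut_offset
        if start < 0 or start + k > amplicon_length:
            raise GenerationError(
                f"cut position {p}: recognition site would extend past the amplicon"
            )
    for a, b in zip(cuts, cuts[1:]):
        if b - a < k:
            raise GenerationError(
                f"cut positions {a} and {b} closer than the recognition-site "
                f"length ({k})"
            )


def _plant_and_repair(seq: list[str], cuts, enzyme: EnzymeSpec, rng) -> bool:
    """Plant recognition sites for the requested cuts and remove spurious ones.

    Mutates ``seq`` in place; returns True when digestion yields exactly
    ``cuts``.  Repairs re-randomise one base of a spurious site that lies
    outside every planted footprint.
    """
    k = len(enzyme.recognition)
    L = len(seq)
    footprints = _site_footprints(cuts, enzyme)
    for p in cuts:
        start = p - enzyme.cut_offset
        for off, code in enumerate(enzyme.recognition):
            seq[start + off] = rng.choice(sorted(IUPAC_SETS[code]))
    for _repair in range(20 * L):
        got = digest("".join(seq), enzyme)
        if set(got.cut_positions) == set(cuts):
            return True
        spurious = [p for p in got.cut_positions if p not in cuts]
        if not spurious:
            return False  # a planted site vanished (should not happen)
        p = spurious[0]
        start = p - enzyme.cut_offset
        free = [i for i in range(start, start + k)
                if i not in footprints and 0 <= i < L]
        if not free:
            return False  # spurious site buried in planted ones
        i = int(rng.choice(free))
        seq[i] = rng.choice([b for b in BASES if b != seq[i]])
    return False


def make_template(
    cut_positions,
    amplicon_length: int = 866,
    seed: int = 0,
    enzyme: EnzymeSpec = APOI,
    max_tries: int = 200,
) -> str:
    """Random amplicon whose enzyme digestion yields exactly the given cuts.

    Cut positions are plus-strand prefix lengths; recognition sites are
    planted so each requested cut is induced and a repair loop removes any
    spurious site.  Deterministic for a given seed.
    """
    cuts = tuple(sorted(set(int(p) for p in cut_positions)))
    _validate_cuts(cuts, amplicon_length, enzyme)
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        seq = list(rng.choice(list(BASES), size=amplicon_length))
        if _plant_and_repair(seq, cuts, enzyme, rng):
            return "".join(seq)
    raise GenerationError(
        f"could not place sites for cuts {cuts} within {max_tries} attempts"
    )


def derive_template(
    base: str,
    cut_positions,
    divergence: float = 0.02,
    seed: int = 0,
    enzyme: EnzymeSpec = APOI,
    max_tries: int = 200,
) -> str:
    """A template related to ``base`` but carrying a different cut-position set.

    Emulates sister haplogroups: the returned sequence differs from ``base``
    by roughly ``divergence`` substitutions per site (placed outside the
    recognition-site footprints) plus whatever site edits the new cut set
    requires.  Useful when two generated haplogroups must sit at a realistic,
    non-saturated distance for tree or network comparisons.
    """
    cuts = tuple(sorted(set(int(p) for p in cut_positions)))
    L = len(base)
    _validate_cuts(cuts, L, enzyme)
    rng = np.random.default_rng(seed)
    footprints = _site_footprints(cuts, enzyme)
    n_sub = int(round(divergence * L))
    for _ in range(max_tries):
        seq = list(base)
        free = [i for i in range(L) if i not in footprints]
        for i in map(int, rng.choice(free, size=min(n_sub, len(free)),
                                     replace=False)):
            seq[i] = rng.choice([b for b in BASES if b != seq[i]])
        if _plant_and_repair(seq, cuts, enzyme, rng):
            return "".join(seq)
    raise GenerationError(
        f"could not derive a template with cuts {cuts} within {max_tries} attempts"
    )


def _resolve_frequencies(config: GeneratorConfig) -> tuple[int, ...]:
    if isinstance(config.haplotype_frequencies, tuple):
        return config.haplotype_frequencies
    freqs, _ = frequencies_for_target_hd(
        config.n_specimens, config.n_haplotypes, config.target_hd
    )
    return freqs


def _resolve_mutations(config: GeneratorConfig,
                       frequencies: tuple[int, ...]) -> tuple[int, ...]:
    m = config.mutations_per_haplotype
    h = config.n_haplotypes
    if isinstance(m, tuple):
        if len(m) != h or m[0] != 0 or any(x < 1 for x in m[1:]):
            raise GenerationError(
                "mutation vector must have n_haplotypes entries, 0 first, >=1 after"
            )
        return m
    if isinstance(m, int):
        if m < 1 and h > 1:
            raise GenerationError("mutations_per_haplotype must be >= 1")
        return (0,) + (m,) * (h - 1)
    return mutations_for_target_pi(frequencies, config.amplicon_length,
                                   config.target_pi)


def mutate_population(
    template: str,
    config: GeneratorConfig,
    enzyme: EnzymeSpec = APOI,
) -> list[SpecimenRecord]:
    """Derive a specimen population from a template (see :func:`generate_population`)."""
    return list(generate_population(config, template=template, enzyme=enzyme).records)


def generate_population(
    config: GeneratorConfig,
    template: str | None = None,
    enzyme: EnzymeSpec = APOI,
) -> SyntheticPopulation:
    """Generate a full synthetic population with ground truth.

    Haplotype 0 is the template itself; each further haplotype carries its own
    private substitutions at positions drawn without replacement from the
    non-site, non-primer interior, so pairwise haplotype distances are exactly
    the sums of mutation counts (star genealogy).  Specimens are assigned to
    haplotypes according to the frequency vector.  Reproducible by seed.
    """
    master = np.random.SeedSequence(config.seed)
    streams = master.spawn(config.n_haplotypes + 2)
    rng_flank = np.random.default_rng(streams[0])

    if template is None:
        template = make_template(
            config.cut_positions, config.amplicon_length,
            seed=int(master.generate_state(1)[0] % (2**31)), enzyme=enzyme,
        )
    L = config.amplicon_length
    if len(template) != L:
        raise GenerationError("template length does not match amplicon_length")

    frequencies = _resolve_frequencies(config)
    mutations = _resolve_mutations(config, frequencies)

    footprints = _site_footprints(config.cut_positions, enzyme)
    pl = config.primer_length
    allowed = [
        i for i in range(pl, L - pl)
        if config.allow_site_mutations or i not in footprints
    ]
    total_mut = sum(mutations)
    if total_mut > len(allowed):
        raise GenerationError(
            f"mutation budget {total_mut} exceeds {len(allowed)} available positions"
        )
    rng_pos = np.random.default_rng(streams[1])
    positions = list(map(int, rng_pos.choice(allowed, size=total_mut, replace=False)))

    template_cuts = digest(template, enzyme).cut_positions
    haplotypes = [template]
    pool = positions
    offset = 0
    for h_idx in range(1, config.n_haplotypes):
        m = mutations[h_idx]
        rng_h = np.random.default_rng(streams[h_idx + 1])
        for _attempt in range(50):
            chosen = pool[offset : offset + m]
            seq = list(template)
            for pos in chosen:
                seq[pos] = rng_h.choice([b for b in BASES if b != template[pos]])
            hap = "".join(seq)
            if digest(hap, enzyme).cut_positions == template_cuts:
                break
            # a substitution created/destroyed a site: redraw replacement
            # positions from the unused tail of the pool
            remaining = [p for p in pool[offset + m:] if p not in chosen]
            extra = [p for p in allowed if p not in pool]
            rng_h.shuffle(extra)
            replacements = (remaining + extra)[:m]
            if len(replacements) < m:
                raise GenerationError("ran out of usable mutation positions")
            pool[offset : offset + m] = replacements
        else:
            raise GenerationError(
                f"could not place cut-site-preserving mutations for haplotype {h_idx}"
            )
        haplotypes.append(hap)
        offset += m

    lf, rf = config.flank_lengths
    left = "".join(rng_flank.choice(list(BASES), size=lf))
    right = "".join(rng_flank.choice(list(BASES), size=rf))
    fwd_primer = template[:pl]
    rev_primer = _revcomp(template[-pl:])

    records: list[SpecimenRecord] = []
    assignments: list[int] = []
    spec_no = 0
    for h_idx, freq in enumerate(frequencies):
        for _ in range(freq):
            spec_no += 1
            records.append(
                SpecimenRecord(
                    specimen_id=f"{config.label}-{spec_no:03d}",
                    sequence=left + haplotypes[h_idx] + right,
                    region=config.region,
                    locality=config.locality,
                    host_plant=config.host_plant,
                    setting=config.setting,
                    year=config.year,
                )
            )
            assignments.append(h_idx)
    return SyntheticPopulation(
        config=config,
        template=template,
        haplotype_sequences=tuple(haplotypes),
        frequencies=tuple(frequencies),
        mutation_counts=tuple(mutations),
        records=tuple(records),
        fwd_primer=fwd_primer,
        rev_primer=rev_primer,
        assignments=tuple(assignments),
    )


def _revcomp(seq: str) -> str:
    from .iupac import reverse_complement

    return reverse_complement(seq)


# ---------------------------------------------------------------------------
# Survey-structure presets
# ---------------------------------------------------------------------------

MEDQ1_CUTS = (252, 296, 562, 654)
MEDQ1_SARDINIAN_CUTS = (252, 296, 562, 654, 672)
MEDQ2_CUTS = (252, 296, 654)


def medq1_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """MEDQ1-like population: 31 specimens, 13 haplotypes, Hd ~ 0.908, pi ~ 0.004."""
    kwargs = dict(
        label="MEDQ1",
        cut_positions=MEDQ1_CUTS,
        n_specimens=31,
        n_haplotypes=13,
        target_hd=0.908,
        target_pi=0.004,
        seed=seed,
        setting="open_field",
        region="Sardinia",
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def medq2_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """MEDQ2-like population: 23 specimens, 3 haplotypes (19/3/1), Hd ~ 0.312."""
    kwargs = dict(
        label="MEDQ2",
        cut_positions=MEDQ2_CUTS,
        n_specimens=23,
        n_haplotypes=3,
        haplotype_frequencies=(19, 3, 1),
        target_pi=0.0004,
        seed=seed,
        setting="greenhouse",
        region="Tuscany",
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)


def medq1_sardinian_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Sardinian MEDQ1 variant: the extra ApoI site at position 672."""
    kwargs = dict(
        label="MEDQ1-Sardinian",
        cut_positions=MEDQ1_SARDINIAN_CUTS,
        n_specimens=5,
        n_haplotypes=2,
        haplotype_frequencies=(4, 1),
        mutations_per_haplotype=1,
        seed=seed,
        setting="open_field",
        region="Sardinia",
    )
    kwargs.update(overrides)
    return GeneratorConfig(**kwargs)
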