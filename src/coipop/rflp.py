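"""In-silico PCR-RFLP typing of COI amplicons.

Emulates the diagnostic assay used to discriminate *Bemisia tabaci*
cryptic species and MED haplogroups: locate the primers, extract the
866-bp COI amplicon, digest it with ApoI (R^AATTY) and classify the
fragment pattern against a library of diagnostic patterns.

Cut positions are expressed as 1-based prefix lengths: the number of
bases 5' of the cut on the plus strand.  With that convention the three
MED diagnostic patterns reproduce the published fragment arithmetic
exactly (e.g. cuts 252, 296, 562, 654 on an 866-bp amplicon give
fragments 252 + 44 + 266 + 92 + 212 = 866).  Double-strand overhangs
are ignored; a fragment length is the distance between successive
plus-strand cut points.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .errors import ConfigurationError, DigestionError, ExtractionError
from .iupac import (
    IUPAC_CODES,
    UNAMBIGUOUS,
    code_subset,
    codes_intersect,
    reverse_complement,
)

__all__ = [
    "EnzymeSpec",
    "APOI",
    "AmpliconSeq",
    "DigestResult",
    "RflpPattern",
    "PatternLibrary",
    "ClassificationResult",
    "MED_LIBRARY",
    "find_primer_sites",
    "extract_amplicon",
    "digest",
    "classify_pattern",
]


@dataclass(frozen=True)
class EnzymeSpec:
    """A restriction endonuclease: IUPAC recognition string + plus-strand cut offset."""

    name: str
    recognition: str = "RAATTY"
    cut_offset: int = 1

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if not rec or any(c not in IUPAC_CODES for c in rec):
            raise ConfigurationError(
                f"enzyme {self.name}: recognition {self.recognition!r} is not IUPAC"
            )
        object.__setattr__(self, "recognition", rec)
        if not 0 <= self.cut_offset <= len(rec):
            raise ConfigurationError(
                f"enzyme {self.name}: cut_offset {self.cut_offset} outside "
                f"[0, {len(rec)}]"
            )


#: ApoI, the diagnostic enzyme of the assay (R^AATTY).
APOI = EnzymeSpec(name="ApoI", recognition="RAATTY", cut_offset=1)


@dataclass(frozen=True)
class AmpliconSeq:
    specimen_id: str
    sequence: str
    source_interval: tuple[int, int]  # half-open, 0-based on the input sequence
    primer_mismatches: tuple[int, int] = (0, 0)
    pre_cut: bool = False  # input was already an amplicon; primers not searched

    def __post_init__(self) -> None:
        lo, hi = self.source_interval
        if hi - lo != len(self.sequence):
            raise ValueError("amplicon length does not match its source interval")


@dataclass(frozen=True)
class DigestResult:
    specimen_id: str
    amplicon_length: int
    cut_positions: tuple[int, ...]  # sorted prefix lengths, exclusive of 0 and L
    fragments: tuple[int, ...]  # sorted multiset of fragment lengths

    def __post_init__(self) -> None:
        if sum(self.fragments) != self.amplicon_length:
            raise ValueError("fragment lengths do not sum to the amplicon length")
        if len(self.fragments) != len(self.cut_positions) + 1:
            raise ValueError("fragment count inconsistent with cut count")
        if any(f < 1 for f in self.fragments):
            raise ValueError("zero-length fragment")


def fragments_from_cuts(cut_positions: tuple[int, ...] | list[int] | set[int],
                        amplicon_length: int) -> tuple[int, ...]:
    """Fragment-length multiset induced by prefix-length cuts on an amplicon."""
    cuts = sorted(set(cut_positions))
    bounds = [0, *cuts, amplicon_length]
    return tuple(sorted(b - a for a, b in zip(bounds, bounds[1:])))


@dataclass(frozen=True)
class RflpPattern:
    """A named diagnostic pattern: taxon label <-> cut-position set <-> fragments."""

    label: str
    cut_positions: frozenset[int]
    amplicon_length: int = 866

    @property
    def expected_fragments(self) -> tuple[int, ...]:
        return fragments_from_cuts(self.cut_positions, self.amplicon_length)


@dataclass
class PatternLibrary:
    patterns: list[RflpPattern] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.patterns]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate pattern labels: {labels}")
        # self-consistency: fragments regenerate from cuts and sum to length
        for p in self.patterns:
            frags = p.expected_fragments
            if sum(frags) != p.amplicon_length:
                raise ConfigurationError(
                    f"pattern {p.label}: fragments {frags} do not sum to "
                    f"{p.amplicon_length}"
                )

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)


#: The three MED diagnostic ApoI patterns on the 866-bp COI amplicon.
#: MEDQ1: fragments 44/92/212/252/266; the Sardinian MEDQ1 variant carries one
#: extra cut at 672 (an 18-bp fragment invisible on gel); MEDQ2: 44/212/252/358.
MED_LIBRARY = PatternLibrary(
    [
        RflpPattern("MEDQ1", frozenset({252, 296, 562, 654})),
        RflpPattern("MEDQ1-Sardinian", frozenset({252, 296, 562, 654, 672})),
        RflpPattern("MEDQ2", frozenset({252, 296, 654})),
    ]
)

MATCH_MODES = ("cut_set_exact", "fragment_multiset", "gel_visible_fragments")


@dataclass(frozen=True)
class ClassificationResult:
    specimen_id: str
    label: str  # pattern label or "unclassified"
    match_mode: str
    distance_to_best: int
    runner_up: tuple[str, int] | None = None


def _match_window(window: str, pattern: str) -> bool:
    """Possible match: every window code's base set intersects the pattern code's."""
    return all(codes_intersect(w, p) for w, p in zip(window, pattern))


def _certain_window(window: str, pattern: str) -> bool:
    """Certain match: every window code's base set is contained in the pattern's."""
    return all(code_subset(w, p) for w, p in zip(window, pattern))


def find_primer_sites(
    sequence: str, primer: str, max_mismatch: int = 0
) -> list[tuple[str, int, int]]:
    """Find all primer binding sites on both strands.

    Returns ``(strand, start, mismatches)`` triples sorted by start position,
    where ``strand`` is ``'+'`` for the primer matching the plus strand and
    ``'-'`` for its reverse complement.  Matching is IUPAC-aware: a position
    counts as a match when the base sets denoted by the two codes intersect.
    """
    primer = primer.upper()
    if len(primer) < 10:
        raise ConfigurationError(f"primer {primer!r} shorter than 10 nt")
    sequence = sequence.upper()
    hits: list[tuple[str, int, int]] = []
    queries = [("+", primer), ("-", reverse_complement(primer))]
    k = len(primer)
    for strand, query in queries:
        for start in range(len(sequence) - k + 1):
            window = sequence[start : start + k]
            mism = sum(
                not codes_intersect(w, q) for w, q in zip(window, query)
            )
            if mism <= max_mismatch:
                hits.append((strand, start, mism))
    hits.sort(key=lambda h: (h[1], h[0]))
    return hits


def extract_amplicon(
    sequence: str,
    fwd_primer: str | None,
    rev_primer: str | None,
    specimen_id: str = "",
    max_mismatch: int = 0,
    expected_length: int = 866,
    tolerance: int = 20,
) -> AmpliconSeq:
    """Extract the PCR product from a longer sequence.

    The amplicon runs from the first base of a plus-strand forward-primer hit
    to the last base of a minus-strand reverse-primer hit (primers included).
    Among all such pairs the one whose product length is nearest
    ``expected_length`` is chosen; only products within ``tolerance`` of the
    expected length are acceptable.

    A sequence that is already exactly ``expected_length`` long and yields no
    primer pair (or has no primers configured) is passed through unchanged and
    flagged ``pre_cut``.
    """
    sequence = sequence.upper().replace("-", "")
    candidates: list[tuple[int, int, int, int, int]] = []
    if fwd_primer and rev_primer:
        fwd_hits = [h for h in find_primer_sites(sequence, fwd_primer, max_mismatch)
                    if h[0] == "+"]
        rev_hits = [h for h in find_primer_sites(sequence, rev_primer, max_mismatch)
                    if h[0] == "-"]
        rev_len = len(rev_primer)
        for _, fstart, fmism in fwd_hits:
            for _, rstart, rmism in rev_hits:
                end = rstart + rev_len  # half-open end = last base of rev hit + 1
                length = end - fstart
                if length <= 0:
                    continue
                if abs(length - expected_length) <= tolerance:
                    candidates.append(
                        (abs(length - expected_length), fstart, end, fmism, rmism)
                    )
    if candidates:
        candidates.sort()
        _, fstart, end, fmism, rmism = candidates[0]
        return AmpliconSeq(
            specimen_id=specimen_id,
            sequence=sequence[fstart:end],
            source_interval=(fstart, end),
            primer_mismatches=(fmism, rmism),
        )
    if len(sequence) == expected_length:
        return AmpliconSeq(
            specimen_id=specimen_id,
            sequence=sequence,
            source_interval=(0, expected_length),
            pre_cut=True,
        )
    raise ExtractionError(
        f"specimen {specimen_id!r}: no primer pair yields a product within "
        f"{tolerance} bp of {expected_length} bp "
        f"(sequence length {len(sequence)})"
    )


def digest(amplicon: AmpliconSeq | str, enzyme: EnzymeSpec = APOI,
           specimen_id: str | None = None) -> DigestResult:
    """Digest an amplicon, returning cut prefix-lengths and fragment lengths.

    The recognition string is matched on the plus strand; each match at
    ``start`` contributes the cut position ``start + cut_offset``.  Overlapping
    matches each contribute their own cut; duplicates collapse.  An ambiguity
    code that makes a potential site undecidable (the window matches under
    some but not all expansions) raises :class:`DigestionError` naming the
    position.
    """
    if isinstance(amplicon, AmpliconSeq):
        seq = amplicon.sequence
        sid = amplicon.specimen_id
    else:
        seq = str(amplicon).upper()
        sid = specimen_id or ""
    seq = seq.replace("-", "")
    rec = enzyme.recognition
    k = len(rec)
    L = len(seq)
    cuts: set[int] = set()
    for start in range(L - k + 1):
        window = seq[start : start + k]
        if _match_window(window, rec):
            if not _certain_window(window, rec):
                raise DigestionError(
                    f"specimen {sid!r}: ambiguity code at potential "
                    f"{enzyme.name} site starting at position {start + 1} "
                    f"(window {window!r}) makes the digest undecidable"
                )
            pos = start + enzyme.cut_offset
            if 0 < pos < L:
                cuts.add(pos)
        elif any(c not in UNAMBIGUOUS for c in window):
            # ambiguity present but no expansion matches: site certainly absent
            continue
    cut_positions = tuple(sorted(cuts))
    return DigestResult(
        specimen_id=sid,
        amplicon_length=L,
        cut_positions=cut_positions,
        fragments=fragments_from_cuts(cut_positions, L),
    )


def _visible(fragments: tuple[int, ...], gel_min_visible: int) -> tuple[int, ...]:
    return tuple(f for f in fragments if f >= gel_min_visible)


def classify_pattern(
    result: DigestResult,
    library: PatternLibrary = MED_LIBRARY,
    mode: str = "cut_set_exact",
    gel_min_visible: int = 25,
) -> ClassificationResult:
    """Classify a digest against the pattern library.

    ``cut_set_exact`` matches on identical cut-position sets,
    ``fragment_multiset`` on identical fragment multisets, and
    ``gel_visible_fragments`` on fragment multisets after discarding
    fragments shorter than ``gel_min_visible`` from both the digest and
    the pattern (mirroring what a gel actually shows).  A label is
    assigned only on a perfect (distance-0) unique match; ties yield
    ``"unclassified"`` with both candidates reported.
    """
    if len(library) == 0:
        raise ConfigurationError("classification requires a non-empty pattern library")
    if mode not in MATCH_MODES:
        raise ConfigurationError(f"unknown match mode {mode!r}; use one of {MATCH_MODES}")

    scored: list[tuple[int, str]] = []
    for pat in library:
        if mode == "cut_set_exact":
            dist = len(set(result.cut_positions) ^ set(pat.cut_positions))
        else:
            obs = Counter(result.fragments)
            exp = Counter(pat.expected_fragments)
            if mode == "gel_visible_fragments":
                obs = Counter(_visible(result.fragments, gel_min_visible))
                exp = Counter(_visible(pat.expected_fragments, gel_min_visible))
            dist = sum(((obs - exp) + (exp - obs)).values())
        scored.append((dist, pat.label))
    scored.sort()
    best_dist, best_label = scored[0]
    runner_up = (scored[1][1], scored[1][0]) if len(scored) > 1 else None
    tie = len(scored) > 1 and scored[1][0] == best_dist
    if best_dist == 0 and not tie:
        label = best_label
    else:
        label = "unclassified"
    return ClassificationResult(
        specimen_id=result.specimen_id,
        label=label,
        match_mode=mode,
        distance_to_best=best_dist,
        runner_up=runner_up,  # type: ignore[arg-type]
    )
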