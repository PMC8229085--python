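import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coipop.errors import ConfigurationError, DigestionError, ExtractionError
from coipop.rflp import (
    APOI,
    MED_LIBRARY,
    DigestResult,
    EnzymeSpec,
    PatternLibrary,
    RflpPattern,
    classify_pattern,
    digest,
    extract_amplicon,
    find_primer_sites,
    fragments_from_cuts,
)
from oracles import digest_cuts_by_expansion, primer_hits_brute

dna = st.text(alphabet="ACGT", min_size=30, max_size=200)


# --- primer search --------------------------------------------------------

def test_planted_unique_primer_found_at_known_offset():
    rng = random.Random(5)
    seq = "".join(rng.choice("ACGT") for _ in range(300))
    primer = seq[137:157]
    hits = [h for h in find_primer_sites(seq, primer, 0) if h[0] == "+"]
    assert ("+", 137, 0) in hits


def test_iupac_ambiguity_matches_every_denoted_base():
    # R matches G with zero mismatches
    hits = find_primer_sites("CCCCAGAATTCCCC", "ARAATTCCCC", 0)
    assert any(h[2] == 0 and h[0] == "+" for h in hits)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(dna, st.integers(0, 2))
def test_primer_search_equals_sliding_window_oracle(seq, max_mismatch):
    primer = seq[7:22]
    assert find_primer_sites(seq, primer, max_mismatch) == primer_hits_brute(
        seq, primer, max_mismatch
    )


def test_primer_shorter_than_10_rejected():
    with pytest.raises(ConfigurationError):
        find_primer_sites("ACGT" * 10, "ACGTACGT", 0)


# --- amplicon extraction --------------------------------------------------

def _construct(amplicon, left, right):
    return left + amplicon + right


def test_planted_flank_construct_extracts_planted_interval():
    rng = random.Random(9)
    amp = "".join(rng.choice("ACGT") for _ in range(866))
    left = "".join(rng.choice("ACGT") for _ in range(80))
    right = "".join(rng.choice("ACGT") for _ in range(60))
    fwd = amp[:20]
    rev_rc = amp[-20:]
    rev = rev_rc.translate(str.maketrans("ACGT", "TGCA"))[::-1]
    got = extract_amplicon(_construct(amp, left, right), fwd, rev, "sp")
    assert got.sequence == amp
    assert got.source_interval == (80, 80 + 866)
    assert not got.pre_cut


def test_bare_expected_length_sequence_passes_through_flagged():
    rng = random.Random(10)
    amp = "".join(rng.choice("ACGT") for _ in range(866))
    got = extract_amplicon(amp, None, None, "sp")
    assert got.pre_cut and got.sequence == amp


def test_two_forward_hits_choose_product_length_nearest_expected():
    rng = random.Random(11)
    amp = "".join(rng.choice("ACGT") for _ in range(866))
    fwd = amp[:20]
    rev = amp[-20:].translate(str.maketrans("ACGT", "TGCA"))[::-1]
    # spurious forward hit planted 120 bp upstream of the true one
    seq = fwd + "".join(rng.choice("ACGT") for _ in range(100)) + amp
    got = extract_amplicon(seq, fwd, rev, "sp")
    assert len(got.sequence) == 866
    assert got.source_interval[0] == 120
    # oracle: enumerate all pairs and confirm the argmin product length
    fhits = [h for h in find_primer_sites(seq, fwd, 0) if h[0] == "+"]
    rhits = [h for h in find_primer_sites(seq, rev, 0) if h[0] == "-"]
    lengths = [
        rs + 20 - fs for _, fs, _ in fhits for _, rs, _ in rhits if rs + 20 > fs
    ]
    assert min(lengths, key=lambda l: abs(l - 866)) == 866


def test_no_primer_pair_and_wrong_length_raises():
    with pytest.raises(ExtractionError):
        extract_amplicon("ACGT" * 40, None, None, "sp")


# --- digestion ------------------------------------------------------------

def test_single_apoi_site_cut_and_fragments():
    # one R^AATTY site with R = G at 1-based prefix 5
    d = digest("AAAAGAATTTCCCC")
    assert d.cut_positions == (5,)
    assert d.fragments == (5, 9)


def test_site_free_sequence_yields_single_fragment():
    d = digest("ACGC" * 50)
    assert d.cut_positions == ()
    assert d.fragments == (200,)


def test_ambiguous_potential_site_raises_naming_position():
    # N at the R position: matches under some expansions only
    with pytest.raises(DigestionError, match="position 5"):
        digest("AAAANAATTTCCCC")


def test_ambiguity_outside_any_potential_site_tolerated():
    d = digest("AAANCCCCGAATTC")
    assert d.cut_positions == (9,)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(dna)
def test_digest_matches_iupac_expansion_oracle(seq):
    d = digest(seq)
    assert list(d.cut_positions) == digest_cuts_by_expansion(seq, "RAATTY", 1)
    assert sum(d.fragments) == len(seq)


def test_overlapping_recognition_matches_each_contribute_a_cut():
    # GAATTAATTC: sites at starts 0 (GAATTA... R=G) and 4? verify via oracle
    seq = "GAATTAATTC" + "C" * 20
    d = digest(seq)
    assert list(d.cut_positions) == digest_cuts_by_expansion(seq, "RAATTY", 1)


def test_digest_result_invariants_enforced():
    with pytest.raises(ValueError):
        DigestResult("x", 10, (5,), (5, 6))  # sums to 11


def test_enzyme_spec_validation():
    with pytest.raises(ConfigurationError):
        EnzymeSpec("bad", "RAATTX", 1)
    with pytest.raises(ConfigurationError):
        EnzymeSpec("bad", "RAATTY", 7)


# --- classification -------------------------------------------------------

def _digest_for(cuts, length=866):
    return DigestResult("sp", length, tuple(sorted(cuts)),
                        fragments_from_cuts(cuts, length))


def test_med_library_self_consistent_fig3_arithmetic():
    expected = {
        "MEDQ1": (44, 92, 212, 252, 266),
        "MEDQ1-Sardinian": (18, 44, 92, 194, 252, 266),
        "MEDQ2": (44, 212, 252, 358),
    }
    for pat in MED_LIBRARY:
        assert pat.expected_fragments == expected[pat.label]
        assert sum(pat.expected_fragments) == 866


def test_medq2_cut_set_classifies():
    res = classify_pattern(_digest_for({252, 296, 654}))
    assert res.label == "MEDQ2" and res.distance_to_best == 0


def test_sardinian_classified_in_gel_visible_mode_without_18bp_piece():
    res = classify_pattern(
        _digest_for({252, 296, 562, 654, 672}),
        mode="gel_visible_fragments", gel_min_visible=25,
    )
    assert res.label == "MEDQ1-Sardinian"
    # oracle: recompute both visible multisets by hand
    sard_visible = tuple(
        f for f in fragments_from_cuts({252, 296, 562, 654, 672}, 866) if f >= 25
    )
    assert sard_visible == (44, 92, 194, 252, 266)
    q1_visible = tuple(
        f for f in fragments_from_cuts({252, 296, 562, 654}, 866) if f >= 25
    )
    assert sard_visible != q1_visible  # still unique after discarding 18 bp


def test_unmatched_digest_is_unclassified_with_runner_up():
    res = classify_pattern(_digest_for({100}))
    assert res.label == "unclassified"
    assert res.distance_to_best > 0
    assert res.runner_up is not None and isinstance(res.runner_up[0], str)


def test_empty_library_is_configuration_error():
    with pytest.raises(ConfigurationError):
        classify_pattern(_digest_for({252}), PatternLibrary([]))


def test_pattern_library_rejects_duplicate_labels():
    with pytest.raises(ConfigurationError):
        PatternLibrary(
            [RflpPattern("X", frozenset({10})), RflpPattern("X", frozenset({20}))]
        )
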