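import itertools
import random

import pytest

from coipop.errors import ConfigurationError, DataError
from coipop.haplonet import (
    edge_cut_groups,
    export_network,
    hamming_matrix,
    import_graphml,
    median_joining,
    spanning_cost,
)
from coipop.popgen import collapse_haplotypes
from oracles import mst_cost, steiner_optimum


# --- distances ------------------------------------------------------------

def test_hamming_matrix_by_inspection():
    m = hamming_matrix(["TAA", "ATA"])
    assert m == [[0, 2], [2, 0]]


def test_hamming_matrix_matches_double_loop_recount():
    rng = random.Random(3)
    haps = list({
        "".join(rng.choice("ACGT") for _ in range(40)) for _ in range(13)
    })
    m = hamming_matrix(haps)
    for i, j in itertools.combinations(range(len(haps)), 2):
        naive = sum(a != b for a, b in zip(haps[i], haps[j]))
        assert m[i][j] == m[j][i] == naive
        for k in range(len(haps)):  # Hamming satisfies the triangle inequality
            assert m[i][j] <= m[i][k] + m[k][j]


def test_hamming_unequal_lengths_is_data_error():
    with pytest.raises(DataError):
        hamming_matrix(["AAA", "AA"])


# --- median joining -------------------------------------------------------

def test_single_haplotype_single_node_no_edges():
    net = median_joining(["ACGT"])
    assert len(net.nodes) == 1 and net.edges == ()
    assert net.nodes[0].kind == "observed"


def test_two_haplotypes_distance_one():
    net = median_joining(["ACGT", "ACGA"])
    assert len(net.nodes) == 2
    assert len(net.edges) == 1 and net.edges[0][2] == 1


def test_equidistant_triple_gains_unique_median():
    """{TAA, ATA, AAT}: one median AAA, three weight-1 edges, cost 3 < MST 4."""
    net = median_joining(["TAA", "ATA", "AAT"])
    medians = [n for n in net.nodes if n.kind == "median"]
    assert len(medians) == 1 and medians[0].sequence == "AAA"
    assert sorted(w for _, _, w in net.edges) == [1, 1, 1]
    assert spanning_cost(net) == 3
    # exhaustive Steiner search confirms 3 is optimal and AAA unique
    assert steiner_optimum(["TAA", "ATA", "AAT"]) == 3


def test_median_addition_never_increases_cost_and_matches_steiner_search():
    rng = random.Random(17)
    for _ in range(12):
        ncols = rng.randint(3, 5)
        nhap = rng.randint(3, 4)
        haps = set()
        while len(haps) < nhap:
            haps.add("".join(rng.choice("AC") for _ in range(ncols)))
        haps = sorted(haps)
        net = median_joining(haps)
        assert spanning_cost(net) <= mst_cost(haps)
        assert spanning_cost(net) == steiner_optimum(haps)


def test_epsilon_monotone_edge_sets(medq1_pop):
    table = collapse_haplotypes(
        [(r.specimen_id, r.sequence) for r in medq1_pop.records]
    )
    haps = [s for _, s, _ in table.haplotypes]
    ids = [h for h, _, _ in table.haplotypes]
    e0 = median_joining(haps, ids=ids, epsilon=0)
    e1 = median_joining(haps, ids=ids, epsilon=1)
    edges0 = {frozenset((a, b)) for a, b, _ in e0.edges}
    edges1 = {frozenset((a, b)) for a, b, _ in e1.edges}
    assert edges0 <= edges1


def test_network_invariants_on_survey_fixture(medq1_pop):
    import networkx as nx

    table = collapse_haplotypes(
        [(r.specimen_id, r.sequence) for r in medq1_pop.records]
    )
    net = median_joining(
        [s for _, s, _ in table.haplotypes], list(table.frequencies),
        ids=[h for h, _, _ in table.haplotypes],
    )
    assert nx.is_connected(net.graph())
    assert all(w >= 1 for _, _, w in net.edges)
    assert sum(n.size for n in net.nodes if n.kind == "observed") == 31
    assert all(n.size == 0 for n in net.nodes if n.kind == "median")
    assert len({n.sequence for n in net.nodes}) == len(net.nodes)


def test_star_like_topology_of_expansion_fixture(medq1_pop):
    """13 haplotypes radiating from a common core form a star-like network."""
    table = collapse_haplotypes(
        [(r.specimen_id, r.sequence) for r in medq1_pop.records]
    )
    net = median_joining(
        [s for _, s, _ in table.haplotypes], list(table.frequencies),
        ids=[h for h, _, _ in table.haplotypes],
    )
    degree: dict[str, int] = {}
    for a, b, _ in net.edges:
        degree[a] = degree.get(a, 0) + 1
        degree[b] = degree.get(b, 0) + 1
    assert max(degree.values()) >= (len(net.nodes) - 1) / 2


def test_traits_change_annotations_not_topology():
    haps = ["TAA", "ATA", "AAT"]
    bare = median_joining(haps)
    traited = median_joining(
        haps, trait_table={"Hap_1": {"Campania": 2}, "Hap_2": {"Latium": 1}}
    )
    assert bare.edges == traited.edges
    assert [n.sequence for n in bare.nodes] == [n.sequence for n in traited.nodes]
    assert dict(traited.nodes[0].traits) == {"Campania": 2}


def test_duplicate_haplotypes_rejected():
    with pytest.raises(DataError):
        median_joining(["AAA", "AAA"])


# --- export ---------------------------------------------------------------

def test_graphml_round_trip_identity(tmp_path):
    net = median_joining(
        ["TAA", "ATA", "AAT"], [3, 2, 1],
        trait_table={"Hap_1": {"Sardinia": 3}},
    )
    path = tmp_path / "net.graphml"
    export_network(net, path, "graphml")
    back = import_graphml(path)
    assert {(n.node_id, n.sequence, n.kind, n.size, n.traits) for n in net.nodes} \
        == {(n.node_id, n.sequence, n.kind, n.size, n.traits) for n in back.nodes}
    assert {tuple(sorted((a, b)) + [w]) for a, b, w in net.edges} \
        == {tuple(sorted((a, b)) + [w]) for a, b, w in back.edges}


def test_nexus_has_traits_block_only_when_traits_present(tmp_path):
    net = median_joining(["TAA", "ATA"], trait_table={"Hap_1": {"Molise": 1}})
    p = tmp_path / "a.nex"
    export_network(net, p, "nexus")
    text = p.read_text()
    assert text.startswith("#NEXUS")
    assert "BEGIN TRAITS;" in text and "TraitLabels Molise" in text
    bare = median_joining(["TAA", "ATA"])
    p2 = tmp_path / "b.nex"
    export_network(bare, p2, "nexus")
    assert "TRAITS" not in p2.read_text()


def test_unknown_export_format_is_configuration_error(tmp_path):
    net = median_joining(["TAA", "ATA"])
    with pytest.raises(ConfigurationError):
        export_network(net, tmp_path / "x", "svg")


def test_edge_cut_groups_partition_nodes():
    net = median_joining(["AAAA", "AAAT", "TTTT"])
    groups = edge_cut_groups(net, max_weight=1)
    all_ids = {n.node_id for n in net.nodes}
    assert set().union(*groups) == all_ids
    assert sum(len(g) for g in groups) == len(all_ids)
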