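import itertools

import networkx as nx
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tcsorg.errors import TCSDataError
from tcsorg.linkage import (
    FocusClusterer,
    build_clusters,
    build_foci,
    compute_intervals,
    focus_size_census,
    partition_dataset,
)

from conftest import make_gene


def genes_from_gaps(gaps, strands, length=500, replicon="rep"):
    """Lay out len(gaps)+1 genes with the given consecutive distances."""
    genes = []
    start = 1000
    for i, strand in enumerate(strands):
        end = start + length - 1
        genes.append(make_gene(f"g{i}", start, end, strand, replicon))
        if i < len(gaps):
            start = end + gaps[i] + 1
    return genes


def oracle_partition(genes, cutoff, same_strand):
    """Brute-force transitive closure over the consecutive-link relation."""
    genes = sorted(genes, key=lambda g: g.sort_key)
    graph = nx.Graph()
    graph.add_nodes_from(g.locus_tag for g in genes)
    for a, b in zip(genes, genes[1:]):
        linked = b.start - a.end - 1 <= cutoff
        if same_strand:
            linked = linked and a.strand == b.strand
        if linked:
            graph.add_edge(a.locus_tag, b.locus_tag)
    return {frozenset(c) for c in nx.connected_components(graph)}


class TestIntervals:
    def test_cis_distance(self, toy_replicon):
        iv = compute_intervals(toy_replicon)
        assert (iv[0].distance_bp, iv[0].orientation) == (50, "cis")

    def test_overlap_is_negative_trans(self):
        genes = [make_gene("g1", 100, 900, "+"), make_gene("g2", 850, 2000, "-")]
        (iv,) = compute_intervals(genes)
        assert (iv.distance_bp, iv.orientation) == (-51, "trans")

    def test_single_gene_empty(self):
        assert compute_intervals([make_gene("g1", 1, 10)]) == []

    def test_circular_wrap(self):
        genes = [make_gene("g1", 100, 900, "+"), make_gene("g2", 5000, 6000, "+")]
        iv = compute_intervals(genes, topology="circular", replicon_length=10000)
        assert iv[-1].wrap
        # 4000 intervening after g2 (6001..10000) plus 99 before g1
        assert iv[-1].distance_bp == 4099

    def test_circular_without_length_errors(self):
        genes = [make_gene("g1", 100, 900), make_gene("g2", 5000, 6000)]
        with pytest.raises(TCSDataError, match="replicon_length"):
            compute_intervals(genes, topology="circular")


class TestPartitions:
    def test_cluster_example(self):
        genes = genes_from_gaps([50, 300, -10], "++++")
        clusters = build_clusters(genes, cutoff_bp=200)
        assert [c.size for c in clusters] == [2, 2]

    def test_strict_cutoff_boundary(self):
        genes = genes_from_gaps([201, 201], "+++")
        assert all(c.size == 1 for c in build_clusters(genes, cutoff_bp=200))
        genes = genes_from_gaps([200, 200], "+++")
        assert [c.size for c in build_clusters(genes, cutoff_bp=200)] == [3]

    def test_strand_breaks_focus_not_cluster(self, toy_replicon):
        clusters = build_clusters(toy_replicon, cutoff_bp=200)
        foci = build_foci(toy_replicon, cutoff_bp=200)
        assert sorted(c.size for c in clusters) == [1, 3]
        assert sorted(f.size for f in foci) == [1, 1, 2]

    def test_circular_wrap_merges(self):
        genes = [make_gene("g1", 100, 900, "+"), make_gene("g2", 9500, 9900, "+")]
        clusters = build_clusters(
            genes, cutoff_bp=200, topology="circular", replicon_length=10000
        )
        assert len(clusters) == 1
        assert clusters[0].members == ("g2", "g1")  # ordered along the run

    def test_minus_strand_strings_read_5prime_to_3prime(self):
        genes = genes_from_gaps([50], "--")
        foci = build_foci(
            genes,
            architectures={"g0": "R", "g1": "T"},
            categories={"g0": "RR", "g1": "HK"},
        )
        (focus,) = foci
        # rightmost gene (g1, the HK) is 5'-most on the minus strand
        assert focus.gene_string == "HK>RR"
        assert focus.domain_string == "T-R"
        assert focus.focus_id == "g1"

    def test_hybrid_renders_as_hk(self):
        genes = genes_from_gaps([], "+")
        (focus,) = build_foci(
            genes, architectures={"g0": "TR"}, categories={"g0": "hybrid_HK"}
        )
        assert focus.gene_string == "HK"
        assert focus.n_domains == 2

    def test_oracle_equivalence_small(self):
        gaps_grid = [-10, 0, 200, 201]
        for n in (2, 3, 4):
            for gaps in itertools.product(gaps_grid, repeat=n - 1):
                for strands in itertools.product("+-", repeat=n):
                    genes = genes_from_gaps(list(gaps), strands)
                    got = {frozenset(c.members) for c in build_clusters(genes, 200)}
                    assert got == oracle_partition(genes, 200, False)
                    got_f = {frozenset(f.members) for f in build_foci(genes, 200)}
                    assert got_f == oracle_partition(genes, 200, True)


@st.composite
def random_replicon(draw):
    n = draw(st.integers(min_value=1, max_value=10))
    gaps = draw(
        st.lists(st.integers(min_value=-60, max_value=1000), min_size=n - 1, max_size=n - 1)
    )
    strands = draw(st.lists(st.sampled_from("+-"), min_size=n, max_size=n))
    return genes_from_gaps(gaps, strands)


class TestProperties:
    @given(random_replicon())
    @settings(max_examples=150, deadline=None)
    def test_partition_and_refinement(self, genes):
        clusters = build_clusters(genes, 200)
        foci = build_foci(genes, 200)
        tags = sorted(g.locus_tag for g in genes)
        assert sorted(t for c in clusters for t in c.members) == tags
        assert sorted(t for f in foci for t in f.members) == tags
        assert len(foci) >= len(clusters)
        cluster_of = {t: i for i, c in enumerate(clusters) for t in c.members}
        for f in foci:  # every focus lies inside one cluster
            assert len({cluster_of[t] for t in f.members}) == 1

    @given(random_replicon())
    @settings(max_examples=100, deadline=None)
    def test_strand_flip_symmetry(self, genes):
        L = max(g.end for g in genes) + 1000
        flipped = [
            make_gene(
                g.locus_tag, L - g.end + 1, L - g.start + 1,
                "-" if g.strand == "+" else "+", g.replicon_id,
            )
            for g in genes
        ]
        arch = {g.locus_tag: "T" for g in genes}
        cats = {g.locus_tag: "HK" for g in genes}
        orig = build_foci(genes, 200, architectures=arch, categories=cats)
        flip = build_foci(flipped, 200, architectures=arch, categories=cats)
        assert {frozenset(f.members) for f in orig} == {
            frozenset(f.members) for f in flip
        }
        assert sorted((f.focus_id, f.gene_string, f.domain_string) for f in orig) == \
            sorted((f.focus_id, f.gene_string, f.domain_string) for f in flip)

    @given(random_replicon())
    @settings(max_examples=100, deadline=None)
    def test_cutoff_monotonicity(self, genes):
        counts = [len(build_foci(genes, c)) for c in (0, 100, 200, 500, 2000)]
        assert counts == sorted(counts, reverse=True)


class TestCensusAndEstimator:
    def test_focus_size_census_ratios(self):
        census = focus_size_census([1, 1, 2, 2, 3])
        by = census.set_index("size")
        assert by.loc["1", "n_genes"] == 2
        assert by.loc["2", "n_genes"] == 4
        assert by.loc["3", "n_genes"] == 3
        assert by.loc["1", "ratio_vs_paired"] == pytest.approx(0.5)
        assert by.loc["3", "ratio_vs_paired"] == pytest.approx(0.75)
        assert census["pct_genes"].sum() == pytest.approx(100.0)

    def test_clusterer_estimator_api(self, toy_replicon):
        from sklearn.base import clone

        model = FocusClusterer(cutoff_bp=200, mode="foci")
        assert clone(model).get_params()["cutoff_bp"] == 200
        labels = model.fit_predict(toy_replicon)
        assert len(labels) == len(toy_replicon)
        assert model.n_partitions_ == 3
        # g1,g2 share a label; g3, g4 are singletons
        assert labels[0] == labels[1] and len(set(labels)) == 3

    def test_partition_dataset_multi_replicon(self):
        a = genes_from_gaps([50], "++", replicon="repA")
        b = [make_gene("h1", 100, 500, "+", "repB")]
        foci = partition_dataset(a + b, mode="foci")
        assert {f.replicon_id for f in foci} == {"repA", "repB"}
        assert sorted(f.size for f in foci) == [1, 2]
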