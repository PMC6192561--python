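"""Network evaluation metrics against enumeration oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from coelnet.evaluation import (
    AnnotationTable,
    degree_publication_bias,
    filter_annotations,
    global_clustering_coefficient,
    jaccard_index,
    neighbor_voting_auroc,
    novelty_fraction,
    robustness_jaccard,
    timesplit_validation_rate,
    withhold_entries,
)
from coelnet.genomic import InteractionCatalog, InteractionRecord

from conftest import make_network


def ann_table(rows):
    return AnnotationTable(
        pd.DataFrame(rows, columns=["protein", "term", "evidence_code"])
    )


class TestAnnotationFiltering:
    def test_broad_term_dropped(self, clique_network):
        # term annotating 6/9 proteins (67%) exceeds the 5% ceiling
        rows = [(p, "broad", "IDA") for p in sorted(clique_network.proteins)[:6]]
        out = filter_annotations(ann_table(rows), clique_network, max_frac=0.05)
        assert len(out) == 0

    def test_evidence_code_filter(self, clique_network):
        rows = [
            ("A1", "t1", "IEA"),             # IEA only -> dropped
            ("A2", "t1", "IEA"),
            ("A2", "t1", "IDA"),             # IEA+EXPerimental -> kept
        ]
        out = filter_annotations(
            ann_table(rows), clique_network, min_frac=0.0, max_frac=1.0
        )
        assert set(out.df["protein"]) == {"A2"}

    def test_boundaries_inclusive(self):
        # 40-protein network; a term with exactly 2 annotations sits on the
        # 5% boundary and is kept
        edges = [(f"N{i:02d}", f"N{i + 1:02d}") for i in range(0, 40, 2)]
        net = make_network(edges)
        rows = [("N00", "t", "IDA"), ("N01", "t", "IDA")]
        out = filter_annotations(ann_table(rows), net, min_frac=0.005,
                                 max_frac=0.05)
        assert len(out) == 2


class TestNeighborVoting:
    def test_clique_term_scores_perfectly(self, clique_network):
        rows = [(p, "termA", "IDA") for p in ["A1", "A2", "A3", "A4"]]
        rows += [(p, "termB", "IDA") for p in ["B1", "B2", "B3", "B4"]]
        per_term, median = neighbor_voting_auroc(
            clique_network, ann_table(rows), n_folds=2, seed=0
        )
        assert per_term.min() == pytest.approx(1.0)
        assert median == pytest.approx(1.0)

    def test_random_labels_near_half(self):
        rng = np.random.default_rng(0)
        aurocs = []
        proteins = [f"P{i:02d}" for i in range(20)]
        g = nx.gnm_random_graph(20, 50, seed=1)
        edges = [(proteins[a], proteins[b]) for a, b in g.edges]
        net = make_network(edges)
        for seed in range(20):
            labels = rng.choice(proteins, size=8, replace=False)
            rows = [(p, "t", "IDA") for p in labels]
            _, median = neighbor_voting_auroc(net, ann_table(rows), n_folds=3,
                                              seed=seed)
            if not np.isnan(median):
                aurocs.append(median)
        assert abs(np.mean(aurocs) - 0.5) < 0.1

    def test_matches_bruteforce_pairwise_oracle(self):
        # 6-node path + chords; deterministic comparison against an
        # all-pairs rank oracle computed by hand below
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"),
                 ("a", "c"), ("d", "f")]
        net = make_network(edges)
        rows = [("a", "t", "IDA"), ("b", "t", "IDA"), ("d", "t", "IDA")]
        per_term, _ = neighbor_voting_auroc(net, ann_table(rows), n_folds=3,
                                            seed=5)

        # oracle: replay the same fold split, score = frac of neighbors
        # annotated in training, AUROC by explicit pairwise comparison
        g = net.graph()
        assign = [("a", "t"), ("b", "t"), ("d", "t")]
        rng = np.random.default_rng(5)
        fold_of = rng.integers(0, 3, size=len(assign))
        fold_aurocs = []
        for f in range(3):
            train = {assign[i][0] for i in range(3) if fold_of[i] != f}
            hidden = {assign[i][0] for i in range(3) if fold_of[i] == f} - train
            negatives = set(g.nodes) - {"a", "b", "d"}
            if not hidden or not train:
                continue
            score = {
                n: sum(nb in train for nb in g.neighbors(n)) / g.degree(n)
                for n in g.nodes
            }
            wins = ties = 0
            for h in hidden:
                for neg in negatives:
                    if score[h] > score[neg]:
                        wins += 1
                    elif score[h] == score[neg]:
                        ties += 1
            fold_aurocs.append(
                (wins + 0.5 * ties) / (len(hidden) * len(negatives))
            )
        assert per_term["t"] == pytest.approx(np.mean(fold_aurocs), abs=1e-12)


def catalog_from(pairs_years, pmids=None):
    records = []
    for i, (a, b, years) in enumerate(pairs_years):
        pm = (pmids[i],) if pmids else (f"PM{i}",)
        records.append(InteractionRecord(a, b, "m", pm, years, "s"))
    return InteractionCatalog(records)


class TestNovelty:
    def test_limits(self):
        net = make_network([("a", "b"), ("c", "d")])
        full = catalog_from([("a", "b", (2010,)), ("c", "d", (2011,))])
        assert novelty_fraction(net, full) == 0.0
        empty = InteractionCatalog([])
        assert novelty_fraction(net, empty) == 1.0

    def test_count_oracle(self):
        edges = [(f"x{i}", f"y{i}") for i in range(10)]
        net = make_network(edges)
        cat = catalog_from([(f"x{i}", f"y{i}", (2012,)) for i in range(4)])
        assert novelty_fraction(net, cat) == pytest.approx(0.6)

    def test_novelty_plus_known_is_one(self):
        edges = [(f"x{i}", f"y{i}") for i in range(7)]
        net = make_network(edges)
        cat = catalog_from([(f"x{i}", f"y{i}", (2012,)) for i in range(3)])
        nov = novelty_fraction(net, cat)
        known = len(net.edge_set & cat.pairs) / len(net.edge_set)
        assert nov + known == pytest.approx(1.0)

    def test_cutoff_restricts_known(self):
        net = make_network([("a", "b")])
        cat = catalog_from([("a", "b", (2018,))])
        assert novelty_fraction(net, cat, cutoff_year=2017) == 1.0
        assert novelty_fraction(net, cat) == 0.0

    def test_empty_network_undefined(self):
        net = make_network([])
        assert np.isnan(novelty_fraction(net, InteractionCatalog([])))


class TestTimesplit:
    def test_limits(self):
        net = make_network([("a", "b"), ("c", "d")])
        nothing_after = catalog_from([("e", "f", (2010,))])
        assert timesplit_validation_rate(net, nothing_after, 2017) == 0.0
        all_rediscovered = catalog_from([("a", "b", (2017,)), ("c", "d", (2018,))])
        assert timesplit_validation_rate(net, all_rediscovered, 2017) == 1.0

    def test_hand_enumerated_mixed_catalog(self):
        net = make_network(
            [("a", "b"), ("c", "d"), ("e", "f"), ("g", "h"), ("i", "j")]
        )
        cat = catalog_from(
            [
                ("a", "b", (2015,)),          # known before cutoff -> not novel
                ("c", "d", (2017,)),          # novel, validated
                ("e", "f", (2015, 2017)),     # known before cutoff -> not novel
                ("g", "h", (2018,)),          # novel, validated (excluded pmid
                                              # applies to c,d's record only)
            ],
            pmids=["P1", "P2", "P3", "P4"],
        )
        # novel = {cd, gh, ij}; validated = {cd, gh} -> 2/3
        rate = timesplit_validation_rate(net, cat, 2017)
        assert rate == pytest.approx(2 / 3)

    def test_circular_pmids_excluded(self):
        net = make_network([("a", "b"), ("c", "d")])
        cat = catalog_from(
            [("a", "b", (2017,)), ("c", "d", (2017,))], pmids=["CIRC", "OK"]
        )
        rate = timesplit_validation_rate(net, cat, 2017, exclude_pmids=["CIRC"])
        # a-b's only support is circular -> dropped; novel = {ab, cd};
        # validated = {cd}
        assert rate == pytest.approx(0.5)

    def test_invariant_to_duplicated_precutoff_records(self):
        net = make_network([("a", "b"), ("c", "d"), ("e", "f")])
        base = [("a", "b", (2015,)), ("c", "d", (2017,))]
        r1 = timesplit_validation_rate(catalog := catalog_from(base), 2017) \
            if False else timesplit_validation_rate(net, catalog_from(base), 2017)
        dup = base + [("a", "b", (2014,)), ("a", "b", (2015,))]
        r2 = timesplit_validation_rate(net, catalog_from(dup), 2017)
        assert r1 == r2

    def test_no_novel_edges_undefined(self):
        net = make_network([("a", "b")])
        cat = catalog_from([("a", "b", (2010,))])
        assert np.isnan(timesplit_validation_rate(net, cat, 2017))


class TestDegreePublicationBias:
    def test_degree_proportional_to_publications(self):
        # star around hub: hub degree 5, leaves degree 1
        edges = [("hub", f"l{i}") for i in range(5)]
        net = make_network(edges)
        pubs = pd.Series({"hub": 100, **{f"l{i}": i + 1 for i in range(5)}})
        rho = degree_publication_bias(net, pubs)
        assert rho > 0.5

    def test_matches_rank_formula_oracle(self):
        rng = np.random.default_rng(3)
        g = nx.gnm_random_graph(10, 20, seed=4)
        names = {i: f"P{i}" for i in g.nodes}
        net = make_network([(names[a], names[b]) for a, b in g.edges])
        pubs = pd.Series(
            rng.integers(1, 100, size=10), index=[f"P{i}" for i in range(10)]
        )
        rho = degree_publication_bias(net, pubs)
        from scipy.stats import spearmanr

        deg = net.degrees()
        oracle = spearmanr(deg.to_numpy(), pubs.reindex(deg.index).to_numpy())[0]
        assert rho == pytest.approx(oracle, abs=1e-12)

    def test_constant_publications_undefined(self):
        net = make_network([("a", "b"), ("b", "c"), ("c", "d")])
        pubs = pd.Series(5, index=["a", "b", "c", "d"])
        with pytest.warns(UserWarning, match="zero variance"):
            assert np.isnan(degree_publication_bias(net, pubs))

    def test_absent_counts_warn_and_default_to_zero(self):
        net = make_network([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        pubs = pd.Series({"a": 3, "b": 7, "c": 11})
        with pytest.warns(UserWarning, match="lack publication"):
            rho = degree_publication_bias(net, pubs)
        assert not np.isnan(rho)


class TestClustering:
    def test_triangle_and_path(self):
        triangle = make_network([("a", "b"), ("b", "c"), ("a", "c")])
        assert global_clustering_coefficient(triangle) == pytest.approx(1.0)
        path = make_network([("a", "b"), ("b", "c")])
        assert global_clustering_coefficient(path) == 0.0

    def test_matches_triple_enumeration_oracle(self):
        g = nx.gnm_random_graph(8, 14, seed=7)
        names = {i: f"P{i}" for i in g.nodes}
        net = make_network([(names[a], names[b]) for a, b in g.edges])
        triangles = sum(
            1
            for trio in itertools.combinations(g.nodes, 3)
            if all(g.has_edge(a, b) for a, b in itertools.combinations(trio, 2))
        )
        triples = sum(
            d * (d - 1) // 2 for _, d in g.degree
        )
        oracle = 3.0 * triangles / triples
        assert global_clustering_coefficient(net) == pytest.approx(oracle,
                                                                   abs=1e-12)

    def test_invariant_to_relabeling(self):
        edges = [("a", "b"), ("b", "c"), ("a", "c"), ("c", "d")]
        net1 = make_network(edges)
        relabel = {"a": "z9", "b": "q2", "c": "m5", "d": "x0"}
        net2 = make_network([(relabel[a], relabel[b]) for a, b in edges])
        assert global_clustering_coefficient(net1) == pytest.approx(
            global_clustering_coefficient(net2)
        )


class TestJaccardRobustness:
    def test_trivial_cases(self):
        n1 = make_network([("a", "b"), ("c", "d")])
        n2 = make_network([("e", "f")])
        assert jaccard_index(n1, n1) == 1.0
        assert jaccard_index(n1, n2) == 0.0
        empty = make_network([])
        assert np.isnan(jaccard_index(empty, empty))

    def test_withhold_zero_identity(self):
        table = pd.DataFrame(
            {"id_a": list("abc"), "id_b": list("xyz"), "score": [1.0, 0.5, 0.2]}
        )
        out = withhold_entries(table, 0.0, np.random.default_rng(0))
        pd.testing.assert_frame_equal(out, table)

    def test_withhold_fraction_of_rows(self):
        table = pd.DataFrame(
            {"id_a": [f"a{i}" for i in range(10)],
             "id_b": [f"b{i}" for i in range(10)],
             "score": np.ones(10)}
        )
        out = withhold_entries(table, 0.2, np.random.default_rng(1))
        assert len(out) == 8

    def test_withhold_protein_unit_drops_all_their_rows(self):
        table = pd.DataFrame(
            {"id_a": ["p1", "p1", "p2", "p3", "p4"],
             "id_b": ["q1", "q2", "q3", "q4", "q5"],
             "score": np.ones(5)}
        )
        out = withhold_entries(table, 0.1, np.random.default_rng(2),
                               unit="protein")
        dropped = set(table["id_a"]) | set(table["id_b"])
        dropped -= set(out["id_a"]) | set(out["id_b"])
        assert dropped  # at least one protein fully removed
        for p in dropped:
            assert not ((out["id_a"] == p) | (out["id_b"] == p)).any()

    def test_no_withholding_gives_all_jaccard_one(self):
        table = pd.DataFrame(
            {"id_a": [f"a{i}" for i in range(6)],
             "id_b": [f"b{i}" for i in range(6)],
             "score": np.linspace(1, 0.5, 6)}
        )

        def pipeline(t):
            return make_network(
                list(zip(t["id_a"], t["id_b"])),
                scores=t["score"].to_numpy(),
            )

        jaccards, median = robustness_jaccard(pipeline, table, withhold=0.0,
                                              repeats=5, seed=3)
        assert len(jaccards) == 10
        assert all(j == 1.0 for j in jaccards)
        assert median == 1.0

    def test_withholding_perturbs_networks(self):
        table = pd.DataFrame(
            {"id_a": [f"a{i}" for i in range(20)],
             "id_b": [f"b{i}" for i in range(20)],
             "score": np.linspace(1, 0.5, 20)}
        )

        def pipeline(t):
            return make_network(
                list(zip(t["id_a"], t["id_b"])), scores=t["score"].to_numpy()
            )

        jaccards, median = robustness_jaccard(pipeline, table, withhold=0.2,
                                              repeats=3, seed=4)
        assert len(jaccards) == 3
        assert all(0.0 <= j < 1.0 for j in jaccards)
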