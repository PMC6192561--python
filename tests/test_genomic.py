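"""External genomic feature construction and catalog semantics."""

import itertools

import numpy as np
import pandas as pd
import pytest

from coelnet.genomic import (
    FEATURE_KINDS,
    FeatureSpec,
    InteractionCatalog,
    InteractionRecord,
    attach_external_features,
    coexpression_scores,
    domain_interaction_indicator,
    interolog_indicator,
    load_pair_score_table,
    phylogenetic_profile_scores,
)


def score_of(table, a, b):
    a, b = sorted((a, b))
    row = table[(table.id_a == a) & (table.id_b == b)]
    return None if row.empty else float(row["score"].iloc[0])


class TestCoexpression:
    def test_duplicated_gene_scores_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        expr = pd.DataFrame([x, x, rng.normal(size=10)], index=["g1", "g2", "g3"])
        t = coexpression_scores(expr)
        assert score_of(t, "g1", "g2") == pytest.approx(1.0)

    def test_negated_gene_scores_minus_one(self):
        x = np.arange(10, dtype=float)
        expr = pd.DataFrame([x, -x], index=["g1", "g2"])
        assert score_of(coexpression_scores(expr), "g1", "g2") == pytest.approx(-1.0)

    def test_matches_formula_oracle(self):
        rng = np.random.default_rng(1)
        expr = pd.DataFrame(rng.normal(size=(5, 10)),
                            index=[f"g{i}" for i in range(5)])
        t = coexpression_scores(expr)
        for a, b in itertools.combinations(expr.index, 2):
            x, y = expr.loc[a].to_numpy(), expr.loc[b].to_numpy()
            oracle = (((x - x.mean()) * (y - y.mean())).sum()
                      / np.sqrt(((x - x.mean()) ** 2).sum()
                                * ((y - y.mean()) ** 2).sum()))
            assert score_of(t, a, b) == pytest.approx(oracle, abs=1e-12)

    def test_constant_gene_has_missing_score(self):
        expr = pd.DataFrame(
            [np.ones(5), np.arange(5.0), np.arange(5.0) ** 2],
            index=["flat", "g1", "g2"],
        )
        t = coexpression_scores(expr)
        assert score_of(t, "flat", "g1") is None
        assert score_of(t, "g1", "g2") is not None

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            coexpression_scores(pd.DataFrame(np.ones((3, 2))))


class TestPhylogeneticProfiles:
    def test_identical_and_complementary_profiles(self):
        p = np.array([1, 0, 1, 1, 0, 0, 1, 0, 1, 0], dtype=float)
        pres = pd.DataFrame([p, p, 1 - p], index=["a", "b", "c"])
        t = phylogenetic_profile_scores(pres)
        assert score_of(t, "a", "b") == pytest.approx(1.0)
        assert score_of(t, "a", "c") == pytest.approx(-1.0)

    def test_matches_phi_coefficient_oracle(self):
        rng = np.random.default_rng(2)
        pres = pd.DataFrame(
            rng.integers(0, 2, size=(6, 20)).astype(float),
            index=[f"p{i}" for i in range(6)],
        )
        pres = pres[pres.std(axis=1) > 0]
        t = phylogenetic_profile_scores(pres)
        for a, b in itertools.combinations(pres.index, 2):
            x, y = pres.loc[a], pres.loc[b]
            n11 = ((x == 1) & (y == 1)).sum()
            n10 = ((x == 1) & (y == 0)).sum()
            n01 = ((x == 0) & (y == 1)).sum()
            n00 = ((x == 0) & (y == 0)).sum()
            phi = (n11 * n00 - n10 * n01) / np.sqrt(
                float((n11 + n10) * (n01 + n00) * (n11 + n01) * (n10 + n00))
            )
            assert score_of(t, a, b) == pytest.approx(phi, abs=1e-12)

    def test_degenerate_profiles_missing(self):
        pres = pd.DataFrame(
            [np.ones(5), np.zeros(5), np.array([1, 0, 0, 1, 0.0])],
            index=["all1", "all0", "ok"],
        )
        t = phylogenetic_profile_scores(pres)
        assert score_of(t, "all1", "ok") is None
        assert score_of(t, "all0", "ok") is None

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            phylogenetic_profile_scores(pd.DataFrame([[0.5, 1.0], [0, 1]]))


class TestDomainIndicator:
    def test_empty_ddi_all_zero(self):
        domains = {"a": {"D1"}, "b": {"D2"}}
        t = domain_interaction_indicator(domains, [])
        assert (t["score"] == 0).all()

    def test_single_interacting_pair(self):
        t = domain_interaction_indicator(
            {"a": {"D1"}, "b": {"D2"}}, [("D1", "D2")]
        )
        assert score_of(t, "a", "b") == 1.0

    def test_self_pair_ddi_allowed(self):
        t = domain_interaction_indicator(
            {"a": {"D1"}, "b": {"D1"}}, [("D1", "D1")]
        )
        assert score_of(t, "a", "b") == 1.0

    def test_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(3)
        all_domains = [f"D{i}" for i in range(8)]
        domains = {
            f"p{i}": set(rng.choice(all_domains, size=rng.integers(1, 4),
                                    replace=False))
            for i in range(10)
        }
        ddi = {
            frozenset(p)
            for p in [("D0", "D3"), ("D1", "D1"), ("D2", "D7"), ("D5", "D6")]
        }
        t = domain_interaction_indicator(domains, [tuple(sorted(p)) for p in ddi])
        for a, b in itertools.combinations(sorted(domains), 2):
            expected = 0.0
            for da in domains[a]:
                for db in domains[b]:
                    if frozenset((da, db)) in ddi:
                        expected = 1.0
            assert score_of(t, a, b) == expected


def toy_catalog():
    """Mixed catalog: two species, varied methods, one bulk publication."""
    bulk = ["BULK1"]  # appears on 26 distinct pairs -> not small-scale
    records = [
        InteractionRecord("x1", "x2", "two hybrid", ("PM1",), (2010,), "other"),
        InteractionRecord("x3", "x4", "Two Hybrid array", ("PM2",), (2012,), "other"),
        InteractionRecord("x5", "x6", "anti bait coimmunoprecipitation",
                          ("PM3",), (2014,), "other"),
        InteractionRecord("x1", "x6", "biochemical", ("PM4",), (2011,), "other"),
        # same species as the study: must be excluded
        InteractionRecord("x7", "x8", "two hybrid", ("PM5",), (2013,), "focal"),
    ]
    for i in range(26):
        records.append(
            InteractionRecord(f"y{i}", f"z{i}", "biochemical", tuple(bulk),
                              (2015,), "other")
        )
    return InteractionCatalog(records)


class TestInterologs:
    ORTHOLOGS = {f"x{i}": f"H{i}" for i in range(1, 9)}

    def test_y2h_substring_match_case_insensitive(self):
        t = interolog_indicator(toy_catalog(), "Y2H", self.ORTHOLOGS, "focal")
        pairs = set(zip(t.id_a, t.id_b))
        assert ("H1", "H2") in pairs and ("H3", "H4") in pairs

    def test_record_in_excluded_species_contributes_nothing(self):
        t = interolog_indicator(toy_catalog(), "Y2H", self.ORTHOLOGS, "focal")
        assert score_of(t, "H7", "H8") is None

    def test_ip_class(self):
        t = interolog_indicator(toy_catalog(), "IP", self.ORTHOLOGS, "focal")
        assert set(zip(t.id_a, t.id_b)) == {("H5", "H6")}

    def test_small_scale_boundary_26_interactions_not_lc(self):
        orths = dict(self.ORTHOLOGS)
        orths.update({f"y{i}": f"Y{i}" for i in range(26)})
        orths.update({f"z{i}": f"Z{i}" for i in range(26)})
        t = interolog_indicator(toy_catalog(), "LC", orths, "focal")
        pairs = set(zip(t.id_a, t.id_b))
        # PM1..PM4 each report one pair -> small scale; BULK1 reports 26 -> not
        assert ("H1", "H2") in pairs
        assert not any(a.startswith("Y") for a, _ in pairs)

    def test_boundary_25_is_small_scale(self):
        records = [
            InteractionRecord(f"a{i}", f"b{i}", "biochemical", ("PMX",), (2010,),
                              "other")
            for i in range(25)
        ]
        cat = InteractionCatalog(records)
        orths = {f"a{i}": f"A{i}" for i in range(25)}
        orths.update({f"b{i}": f"B{i}" for i in range(25)})
        t = interolog_indicator(cat, "LC", orths, "focal")
        assert len(t) == 25

    def test_unmapped_proteins_contribute_nothing(self):
        t = interolog_indicator(toy_catalog(), "Y2H", {"x1": "H1"}, "focal")
        assert t.empty

    def test_full_universe_emits_zeros(self):
        pairs = [("H1", "H2"), ("H1", "H9")]
        t = interolog_indicator(toy_catalog(), "Y2H", self.ORTHOLOGS, "focal",
                                pairs=pairs)
        assert score_of(t, "H1", "H2") == 1.0
        assert score_of(t, "H1", "H9") == 0.0

    def test_species_exclusion_contract_all_zero(self):
        # the catalog's only species is excluded -> empty feature
        records = [
            InteractionRecord("x1", "x2", "two hybrid", ("P",), (2010,), "solo")
        ]
        t = interolog_indicator(
            InteractionCatalog(records), "Y2H", {"x1": "A", "x2": "B"}, "solo"
        )
        assert t.empty


class TestLoadPairScores:
    def test_duplicate_pair_resolved_by_max(self, tmp_path):
        path = tmp_path / "scores.tsv"
        path.write_text("a\tb\t0.2\nb\ta\t0.5\n")
        t = load_pair_score_table(path, "cocitation")
        assert len(t) == 1
        assert score_of(t, "a", "b") == 0.5

    def test_empty_file(self, tmp_path):
        path = tmp_path / "empty.tsv"
        path.write_text("")
        assert load_pair_score_table(path, "fusion").empty

    def test_dedup_count_matches_set_oracle(self, tmp_path):
        rng = np.random.default_rng(4)
        ids = [f"p{i}" for i in range(12)]
        lines, seen = [], set()
        for _ in range(100):
            a, b = rng.choice(ids, size=2, replace=False)
            seen.add(tuple(sorted((a, b))))
            lines.append(f"{a}\t{b}\t{rng.random():.3f}")
        path = tmp_path / "many.tsv"
        path.write_text("\n".join(lines) + "\n")
        t = load_pair_score_table(path, "neighborhood")
        assert len(t) == len(seen)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("a\tb\t0.5\na\tb\n")
        with pytest.raises(ValueError, match=":2:"):
            load_pair_score_table(path, "cocitation")

    def test_out_of_range_score_rejected(self, tmp_path):
        path = tmp_path / "oob.tsv"
        path.write_text("a\tb\t1.5\n")
        with pytest.raises(ValueError, match="outside"):
            load_pair_score_table(path, "cocitation")


class TestAttach:
    @pytest.fixture
    def base(self):
        return pd.DataFrame(
            {"id_a": ["a", "a"], "id_b": ["b", "c"], "pearson_r": [0.9, 0.1]}
        )

    def test_empty_combination_is_identity(self, base):
        out = attach_external_features(base, [], {})
        pd.testing.assert_frame_equal(out, base)

    def test_indicator_column_with_missing(self, base):
        feat = pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "score": [1.0]})
        out = attach_external_features(base, ["domain"], {"domain": feat})
        assert out["domain"].tolist()[0] == 1.0
        assert np.isnan(out["domain"].tolist()[1])

    def test_all_nine_features_give_fifteen_columns(self, base):
        feats = {
            k: pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "score": [0.5]})
            for k in FEATURE_KINDS
        }
        out = attach_external_features(base, list(FEATURE_KINDS), feats)
        assert out.shape[1] == 3 + 9
        assert list(out.columns[-9:]) == list(FEATURE_KINDS)

    def test_duplicate_feature_rejected(self, base):
        with pytest.raises(ValueError, match="duplicate"):
            attach_external_features(base, ["domain", "domain"], {})

    def test_unknown_feature_rejected(self, base):
        with pytest.raises(ValueError, match="unknown"):
            attach_external_features(base, ["astrology"], {})

    def test_feature_spec_objects_accepted(self, base):
        feat = pd.DataFrame({"id_a": ["a"], "id_b": ["b"], "score": [0.3]})
        out = attach_external_features(
            base, [FeatureSpec("cocitation")], {"cocitation": feat}
        )
        assert "cocitation" in out.columns


class TestCatalog:
    def test_pair_queries_order_insensitive(self):
        cat = InteractionCatalog(
            [InteractionRecord("b", "a", "m", ("P1",), (2015,), "s")]
        )
        assert ("a", "b") in cat and ("b", "a") in cat

    def test_known_before_uses_any_year_strictly_before(self):
        cat = InteractionCatalog(
            [
                InteractionRecord("a", "b", "m", ("P1", "P2"), (2015, 2018), "s"),
                InteractionRecord("c", "d", "m", ("P3",), (2018,), "s"),
            ]
        )
        assert cat.pairs_known_before(2017) == {("a", "b")}
        assert cat.pairs_discovered_from(2017) == {("a", "b"), ("c", "d")}
        assert cat.pairs_known_before(None) == {("a", "b"), ("c", "d")}

    def test_without_pmids_drops_only_solely_supported(self):
        cat = InteractionCatalog(
            [
                InteractionRecord("a", "b", "m", ("CIRC",), (2015,), "s"),
                InteractionRecord("c", "d", "m", ("CIRC", "OK"), (2015,), "s"),
            ]
        )
        kept = cat.without_pmids(["CIRC"])
        assert kept.pairs == {("c", "d")}

    def test_roundtrip_tsv(self, tmp_path):
        cat = toy_catalog()
        path = tmp_path / "catalog.tsv"
        cat.to_tsv(path)
        back = InteractionCatalog.from_tsv(path)
        assert back.pairs == cat.pairs
        assert len(back) == len(cat)
        assert back.publication_sizes() == cat.publication_sizes()
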