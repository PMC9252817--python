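"""Hypergeometric test, BH adjustment, and the enrichment model."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gocellmap.annotation import CompartmentGeneSets, GeneUniverse
from gocellmap.enrichment import (
    CleanQuery,
    CompartmentEnrichment,
    bh_fdr,
    effective_universe,
    enrich_compartments,
    enrich_terms,
    highest_enriched,
    hypergeom_pvalue,
    read_table,
    write_table,
)


def enumeration_pvalue(k, K, n, N):
    """Independent oracle: count draws with >= k successes over all C(N, n)
    equally likely subsets of a population whose first K items are successes."""
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if sum(1 for item in draw if item < K) >= k
    )
    return Fraction(hits, math.comb(N, n))


class TestHypergeomPvalue:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_pvalue(0, 4, 5, 10) == 1.0

    def test_degenerate_full_draw_is_certain(self):
        assert hypergeom_pvalue(4, 4, 10, 10) == 1.0

    def test_worked_example_66_of_252(self):
        # N=10, K=4, n=5, k=3: 66 of the 252 possible draws have >= 3 successes
        expected = enumeration_pvalue(3, 4, 5, 10)
        assert expected == Fraction(66, 252)
        assert hypergeom_pvalue(3, 4, 5, 10) == pytest.approx(float(expected), abs=1e-15)

    @pytest.mark.parametrize(
        "k,K,n,N",
        [(-1, 4, 5, 10), (5, 4, 5, 10), (3, 11, 5, 10), (3, 4, 11, 10)],
    )
    def test_domain_errors(self, k, K, n, N):
        with pytest.raises(ValueError):
            hypergeom_pvalue(k, K, n, N)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.data())
    def test_monotone_in_k_and_K(self, data):
        N = data.draw(st.integers(2, 60))
        K = data.draw(st.integers(1, N))
        n = data.draw(st.integers(1, N))
        k = data.draw(st.integers(1, min(K, n)))
        p = hypergeom_pvalue(k, K, n, N)
        # larger observed overlap is never more probable
        assert hypergeom_pvalue(k - 1, K, n, N) >= p
        # a bigger gene set makes the same overlap easier
        if K < N:
            assert hypergeom_pvalue(k, K + 1, n, N) >= p - 1e-12

    def test_large_universe_numerically_safe(self):
        p = hypergeom_pvalue(500, 2000, 1000, 100_000)
        assert np.isfinite(p) and 0.0 < p < 1e-300  # deep tail, yet no underflow to zero


class TestBhFdr:
    def test_single_p_is_identity(self):
        assert bh_fdr([0.03]) == pytest.approx([0.03])

    def test_worked_step_up_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.5]) == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_constant_vector_unchanged(self):
        assert bh_fdr([0.2] * 7) == pytest.approx([0.2] * 7)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0, exclude_min=False), min_size=1, max_size=50))
    def test_dominates_input_and_capped_at_one(self, ps):
        q = bh_fdr(ps)
        assert np.all(q >= np.asarray(ps) - 1e-15)
        assert np.all(q <= 1.0)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-8, 1.0), min_size=2, max_size=20), st.randoms())
    def test_permutation_equivariant(self, ps, rnd):
        order = list(range(len(ps)))
        rnd.shuffle(order)
        q = bh_fdr(ps)
        q_shuffled = bh_fdr([ps[i] for i in order])
        assert q_shuffled == pytest.approx([q[i] for i in order])

    @pytest.mark.parametrize("bad", [[0.0], [1.2], [-0.1], [float("nan")]])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            bh_fdr(bad)


@pytest.fixture(scope="module")
def toy_sets():
    universe = GeneUniverse("synthetic", frozenset(f"G{i:03d}" for i in range(100)))
    sets = {
        "alpha": frozenset(f"G{i:03d}" for i in range(0, 20)),
        "beta": frozenset(f"G{i:03d}" for i in range(10, 40)),
        "gamma": frozenset(f"G{i:03d}" for i in range(50, 60)),
    }
    return CompartmentGeneSets(universe=universe, sets=sets)


class TestEffectiveUniverse:
    def test_without_background_uses_species_universe(self, toy_sets):
        universe, ks = effective_universe(toy_sets)
        assert len(universe) == 100
        assert ks == {"alpha": 20, "beta": 30, "gamma": 10}

    def test_background_equal_to_one_set_makes_it_saturated(self, toy_sets):
        universe, ks = effective_universe(toy_sets, background=toy_sets.sets["gamma"])
        assert ks["gamma"] == len(universe) == 10

    def test_brute_force_intersections(self, toy_sets):
        rng = np.random.default_rng(5)
        genes = sorted(toy_sets.universe.genes)
        background = {genes[i] for i in rng.choice(100, size=40, replace=False)}
        universe, ks = effective_universe(toy_sets, background=background)
        for name, genes_in_set in toy_sets.sets.items():
            assert ks[name] == len(genes_in_set & background)

    def test_disjoint_background_rejected(self, toy_sets):
        with pytest.raises(ValueError, match="no genes"):
            effective_universe(toy_sets, background={"ZZZ"})


class TestEnrichCompartments:
    def test_disjoint_query_all_non_significant(self, toy_sets):
        query = CleanQuery(frozenset({"G090", "G095"}))
        table = enrich_compartments(query, toy_sets)
        assert (table["p_value"] == 1.0).all()
        assert (table["fdr"] == 1.0).all()

    def test_full_set_query_has_minimum_fdr(self, toy_sets):
        query = CleanQuery(toy_sets.sets["gamma"])
        table = enrich_compartments(query, toy_sets)
        assert table.iloc[0]["compartment"] == "gamma"
        assert table.iloc[0]["fdr"] == table["fdr"].min()

    def test_row_fields_consistent(self, toy_sets):
        query = CleanQuery(frozenset({"G000", "G015", "G055"}))
        table = enrich_compartments(query, toy_sets)
        for _, row in table.iterrows():
            assert row["k"] == len(row["overlap_genes"])
            assert 0 <= row["k"] <= min(row["K"], row["n"])
            assert row["fdr"] >= row["p_value"] - 1e-15

    def test_empty_effective_query_raises_advice(self, toy_sets):
        with pytest.raises(ValueError, match="check identifier"):
            enrich_compartments(CleanQuery(frozenset({"NOPE"})), toy_sets)

    def test_shrinking_background_keeps_k(self, toy_sets):
        query = CleanQuery(frozenset({"G000", "G015", "G055"}))
        full = enrich_compartments(query, toy_sets).set_index("compartment")
        background = set(query.genes) | set(list(sorted(toy_sets.universe.genes))[:70])
        restricted = enrich_compartments(query, toy_sets, background=background).set_index(
            "compartment"
        )
        for name in toy_sets.names:
            assert full.loc[name, "k"] == restricted.loc[name, "k"]
        assert (restricted["N"] < full["N"]).all()


class TestEnrichTerms:
    def test_terms_without_query_genes_absent(self, graph, records, model, gene_sets, planted_query):
        query = CleanQuery(frozenset(planted_query))
        table = enrich_terms(query, graph, records, model, gene_sets)
        assert (table["k"] > 0).all()

    def test_compartment_labels_match_model_membership(
        self, graph, records, model, gene_sets, planted_query
    ):
        query = CleanQuery(frozenset(planted_query))
        table = enrich_terms(query, graph, records, model, gene_sets)
        for _, row in table.head(50).iterrows():
            expected = set(model.compartments_of(row["go_id"]))
            labelled = set(row["compartments"].split(";")) if row["compartments"] else set()
            assert labelled == expected

    def test_identical_contingency_identical_p(self, graph, records, model, gene_sets, planted_query):
        query = CleanQuery(frozenset(planted_query))
        table = enrich_terms(query, graph, records, model, gene_sets)
        by_key = table.groupby(["k", "K"])["p_value"].nunique()
        assert (by_key == 1).all()


class TestHighestEnriched:
    def make(self, rows):
        return pd.DataFrame(rows, columns=["compartment", "k", "K", "n", "N", "p_value", "fdr", "overlap_genes"])

    def test_single_row(self):
        table = self.make([("solo", 1, 5, 10, 100, 0.5, 0.5, ["g"])])
        assert highest_enriched(table) == "solo"

    def test_tie_broken_by_larger_overlap(self):
        table = self.make(
            [
                ("small", 3, 50, 10, 100, 0.2, 0.4, ["a"] * 3),
                ("big", 5, 50, 10, 100, 0.2, 0.4, ["b"] * 5),
            ]
        )
        assert highest_enriched(table) == "big"

    def test_full_tie_broken_alphabetically(self):
        table = self.make(
            [
                ("zeta", 3, 50, 10, 100, 0.2, 0.4, ["a"] * 3),
                ("alpha", 3, 50, 10, 100, 0.2, 0.4, ["b"] * 3),
            ]
        )
        assert highest_enriched(table) == "alpha"

    def test_planted_compartment_recovered(self, gene_sets, planted_query, target_compartment):
        table = enrich_compartments(CleanQuery(frozenset(planted_query)), gene_sets)
        assert highest_enriched(table) == target_compartment


class TestModelResults:
    def test_fit_summary_and_roundtrip(self, gene_sets, planted_query, target_compartment, tmp_path):
        results = CompartmentEnrichment(planted_query, gene_sets).fit()
        text = results.summary()
        assert target_compartment in text
        assert f"query: {len(planted_query)} genes" in text
        path = tmp_path / "table.tsv"
        results.to_tsv(path)
        back = read_table(path)
        pd.testing.assert_frame_equal(
            back, results.table, check_dtype=False, check_exact=True
        )

    def test_from_files_matches_in_memory(self, gene_sets, planted_query, tmp_path):
        path = tmp_path / "query.txt"
        path.write_text("\n".join(planted_query) + "\n")
        a = CompartmentEnrichment.from_files(path, gene_sets).fit()
        b = CompartmentEnrichment(planted_query, gene_sets).fit()
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_cleaning_report_surfaces_drops(self, gene_sets, planted_query):
        noisy = list(planted_query) + [planted_query[0], "NOT_A_GENE"]
        model = CompartmentEnrichment(noisy, gene_sets)
        assert model.query.report.duplicates == [planted_query[0]]
        assert model.query.report.invalid == ["NOT_A_GENE"]
        assert len(model.query) == len(planted_query)
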