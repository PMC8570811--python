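"""Contingency construction, Fisher/OR/chi2, BH adjustment, enrichment runs."""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from chemlit import (
    ContingencyTable,
    EnrichmentConfig,
    EntityId,
    KnowledgeGraph,
    bh_qvalues,
    build_contingency,
    build_corpus_index,
    chi_squared,
    compare_significant,
    enumerate_candidate_pairs,
    fisher_right_tail,
    odds_ratio,
    run_enrichment,
)
from chemlit.synthetic import SyntheticConfig, generate

from conftest import random_graph


def exact_right_tail(a: int, b: int, c: int, d: int) -> float:
    """Independent oracle: exact rational tail sum of the hypergeometric pmf."""
    n, big_k, big_n = a + b, a + c, a + b + c + d
    denom = math.comb(big_n, n)
    total = Fraction(0)
    for x in range(a, min(n, big_k) + 1):
        total += Fraction(math.comb(big_k, x) * math.comb(big_n - big_k, n - x), denom)
    return float(total)


class TestContingency:
    def test_disjoint_corpora(self):
        kg = KnowledgeGraph()
        arts = [f"PMID{i}" for i in range(10)]
        kg.articles.update(arts)
        comp = EntityId("compound:CID1")
        kg.compounds.add(comp)
        d = kg.add_descriptor("mesh:D000001", ["C01"])
        for art in arts[:5]:
            kg.discusses.add((art, comp))
        for art in arts[5:8]:
            kg.subject_terms.add((art, d))
        index = build_corpus_index(kg)
        t = build_contingency(index, comp, d)
        assert (t.a, t.b, t.c, t.d) == (0, 5, 3, 2)

    def test_margins_recover_corpus_sizes(self, rng):
        kg = random_graph(rng)
        index = build_corpus_index(kg)
        for comp in sorted(kg.compounds)[:6]:
            for d in sorted(kg.descriptors)[:6]:
                t = build_contingency(index, comp, d)
                assert t.n_chem == len(index.propagated[comp])
                assert t.n_mesh == len(index.propagated[d])
                assert t.n == index.n_universe
                assert t.a == len(index.propagated[comp] & index.propagated[d])

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            ContingencyTable(1, -1, 0, 0)


class TestFisherRightTail:
    def test_zero_support_gives_one(self):
        assert fisher_right_tail(ContingencyTable(0, 5, 3, 2)) == 1.0

    def test_small_table_exact_value(self):
        # tail of Hypergeom(N=8, K=4, n=4) at a >= 3: (16 + 1)/70
        assert fisher_right_tail(ContingencyTable(3, 1, 1, 3)) == pytest.approx(17 / 70, rel=1e-12)

    def test_agrees_with_scipy_fisher(self, rng):
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(0, 40, size=4))
            ours = fisher_right_tail(ContingencyTable(a, b, c, d))
            ref = scipy.stats.fisher_exact([[a, b], [c, d]], alternative="greater")[1]
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_large_universe_stability(self):
        """Survival values stay finite and ordered for universes ~1e7."""
        t = ContingencyTable(5000, 95000, 400000, 9_500_000)
        p = fisher_right_tail(t)
        assert 0.0 <= p <= 1.0
        stronger = ContingencyTable(5500, 94500, 399500, 9_500_500)
        assert fisher_right_tail(stronger) <= p

    @given(st.integers(1, 15), st.integers(0, 15), st.integers(0, 15), st.integers(0, 15))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_monotone_in_a_with_margins_fixed(self, a, b, c, d):
        """Shifting one article from discordant cells into a strictly lowers p."""
        if b < 1 or c < 1:
            return
        t = ContingencyTable(a, b, c, d)
        shifted = ContingencyTable(a + 1, b - 1, c - 1, d + 1)  # same margins
        assert fisher_right_tail(shifted) < fisher_right_tail(t)


class TestOddsRatioChi2:
    def test_plain_odds_ratio(self):
        assert odds_ratio(ContingencyTable(3, 1, 1, 3)) == (9.0, False)

    def test_independence_is_one(self):
        assert odds_ratio(ContingencyTable(7, 7, 7, 7)) == (1.0, False)

    def test_haldane_correction_flagged(self):
        value, corrected = odds_ratio(ContingencyTable(0, 5, 3, 2))
        assert corrected
        assert value == pytest.approx((0.5 * 2.5) / (5.5 * 3.5))

    def test_chi2_independence_zero(self):
        assert chi_squared(ContingencyTable(10, 10, 10, 10)) == 0.0

    def test_chi2_hand_value(self):
        assert chi_squared(ContingencyTable(20, 10, 10, 20)) == pytest.approx(20 / 3)

    def test_chi2_zero_margin(self):
        assert chi_squared(ContingencyTable(0, 0, 5, 5)) == 0.0

    def test_chi2_matches_expected_count_oracle(self, rng):
        for _ in range(50):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            n = a + b + c + d
            observed = np.array([[a, b], [c, d]], dtype=float)
            expected = np.outer(observed.sum(axis=1), observed.sum(axis=0)) / n
            oracle = float(((observed - expected) ** 2 / expected).sum())
            assert chi_squared(ContingencyTable(a, b, c, d)) == pytest.approx(oracle)


def naive_bh(pvals):
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q


class TestBH:
    def test_hand_example(self):
        assert bh_qvalues([0.001, 0.01, 0.02, 0.04]) == pytest.approx(
            [0.004, 0.02, 0.02666666666666667, 0.04]
        )

    def test_single_and_empty(self):
        assert bh_qvalues([]) == []
        assert bh_qvalues([0.37]) == [0.37]

    def test_all_equal(self):
        assert bh_qvalues([0.2, 0.2, 0.2]) == pytest.approx([0.2, 0.2, 0.2])

    @given(st.lists(st.floats(1e-12, 1.0), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_matches_naive_stepup_and_dominates_p(self, pvals):
        q = bh_qvalues(pvals)
        assert q == pytest.approx(naive_bh(pvals), rel=1e-10)
        assert all(qi >= pi - 1e-15 for qi, pi in zip(q, pvals))


class TestCandidatePairs:
    def test_class_size_cap_excludes_large_class(self, rng):
        kg = random_graph(rng, n_compounds=12)
        index = build_corpus_index(kg)
        pairs = enumerate_candidate_pairs(kg, index, EnrichmentConfig(class_size_cap=1))
        assert all(chem.entity_kind == "compound" for chem, _ in pairs)
        # with a permissive cap, classes with members reappear
        pairs_cap = enumerate_candidate_pairs(kg, index, EnrichmentConfig(class_size_cap=1000))
        assert any(chem.entity_kind == "chemical_class" for chem, _ in pairs_cap)

    def test_category_filter(self, rng):
        kg = random_graph(rng)
        index = build_corpus_index(kg)
        pairs = enumerate_candidate_pairs(kg, index, EnrichmentConfig(allowed_categories=frozenset("C")))
        letters = {tn[0] for _, mesh in pairs for tn in kg.descriptors[mesh].tree_numbers}
        assert letters <= {"C"}
        # the random forest also grows E trees, which the default set excludes
        all_pairs = enumerate_candidate_pairs(kg, index, EnrichmentConfig(allowed_categories=frozenset("CDE")))
        assert len(all_pairs) >= len(pairs)

    def test_min_support_matches_exhaustive_scan(self, rng):
        kg = random_graph(rng, n_articles=40)
        index = build_corpus_index(kg)
        config = EnrichmentConfig(allowed_categories=frozenset("CDE"))
        pairs = set(enumerate_candidate_pairs(kg, index, config))
        chems = kg.compounds | set(kg.classes)
        oracle = {
            (e, d)
            for e in chems
            for d in kg.descriptors
            if len(index.propagated[e] & index.propagated[d]) >= 1
        }
        assert pairs == oracle

    def test_mesh_mesh_mode_adds_descriptor_pairs(self, rng):
        kg = random_graph(rng)
        index = build_corpus_index(kg)
        pairs = enumerate_candidate_pairs(kg, index, EnrichmentConfig(mesh_mesh=True))
        assert any(chem.entity_kind == "mesh_descriptor" for chem, _ in pairs)


class TestRunEnrichment:
    def test_planted_pair_is_significant_nulls_are_not(self):
        config = SyntheticConfig(
            n_articles=2000,
            planted_pairs=(("compound:CID000001", "mesh:DC000005", 20.0),),
            seed=7,
        )
        kg, truth = generate(config)
        records = run_enrichment(kg)
        by_pair = {(r.chem.curie, r.mesh.curie): r for r in records}
        planted = truth.planted[0]
        assert by_pair[(planted.chem.curie, planted.mesh.curie)].significant
        false_sig = [
            r for r in records if r.significant and (r.chem.curie, r.mesh.curie) not in truth.true_pairs
        ]
        assert false_sig == []

    def test_vacuous_threshold_flags_everything(self):
        kg, _ = generate(SyntheticConfig(n_articles=300, seed=3))
        records = run_enrichment(kg, EnrichmentConfig(q_threshold=1.0, compute_fragility=False))
        assert records and all(r.significant for r in records)

    def test_output_ordering_is_deterministic(self):
        kg, _ = generate(SyntheticConfig(n_articles=400, seed=5))
        r1 = run_enrichment(kg, EnrichmentConfig(compute_fragility=False))
        r2 = run_enrichment(kg, EnrichmentConfig(compute_fragility=False))
        assert [(r.chem, r.mesh) for r in r1] == [(r.chem, r.mesh) for r in r2]
        chis = [r.chi2 for r in r1]
        assert chis == sorted(chis, reverse=True)

    def test_q_dominates_p_and_flag_matches_threshold(self):
        kg, _ = generate(SyntheticConfig(n_articles=400, seed=5))
        config = EnrichmentConfig(q_threshold=0.01, compute_fragility=False)
        for r in run_enrichment(kg, config):
            assert r.q_value >= r.p_value - 1e-15
            assert r.significant == (r.q_value < 0.01)

    def test_per_entity_kind_bh_scope(self):
        kg, _ = generate(SyntheticConfig(n_articles=400, seed=5))
        recs = run_enrichment(
            kg, EnrichmentConfig(bh_scope="per-entity-kind", compute_fragility=False)
        )
        # grouped adjustment still dominates raw p
        assert all(r.q_value >= r.p_value - 1e-15 for r in recs)

    def test_propagation_comparison_partition(self):
        """With ancestor-level signal, propagation yields novel pairs that
        have zero explicit co-occurrence (no direct links without it)."""
        config = SyntheticConfig(
            n_articles=3000,
            planted_pairs=(("compound:CID000001", "mesh:DC000005", 18.0),
                           ("compound:CID000002", "mesh:DC000006", 18.0)),
            seed=11,
        )
        kg, _ = generate(config)
        with_prop = run_enrichment(kg, EnrichmentConfig(compute_fragility=False))
        without_prop = run_enrichment(
            kg, EnrichmentConfig(use_propagation=False, compute_fragility=False)
        )
        report = compare_significant(with_prop, without_prop)
        assert report.novel, "expected ancestor-level associations"
        index = build_corpus_index(kg, use_propagation=False)
        for chem_curie, mesh_curie in report.novel:
            explicit = index.explicit[EntityId(chem_curie)] & index.explicit[EntityId(mesh_curie)]
            assert len(explicit) == 0
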