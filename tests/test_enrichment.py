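"""ORA against an exhaustive-enumeration oracle, BH-FDR, weighted set cover."""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pcosnet import (
    GeneSetCollection,
    bh_fdr,
    enrichment_report,
    hypergeom_ora,
    weighted_set_cover,
)
from pcosnet.enrichment import EnrichmentResult, significant_results


def enumerate_upper_tail(n_univ, n_set, n_study, k) -> Fraction:
    """P[overlap >= k] by enumerating every study draw (independent oracle)."""
    marked = set(range(n_set))
    hits = total = 0
    for draw in combinations(range(n_univ), n_study):
        total += 1
        if len(marked & set(draw)) >= k:
            hits += 1
    return Fraction(hits, total)


def collection_for(n_univ, n_set) -> GeneSetCollection:
    universe = frozenset(f"G{i}" for i in range(n_univ))
    members = frozenset(f"G{i}" for i in range(n_set))
    return GeneSetCollection({"S": ("d", members)}, universe_override=universe)


class TestHypergeomOra:
    def test_worked_example_66_over_252(self):
        """N=10, K=4, n=5, k=3 gives exactly 66/252."""
        coll = collection_for(10, 4)
        study = {"G0", "G1", "G2", "G5", "G6"}  # 3 of the 4 marked genes
        (res,) = hypergeom_ora(study, coll)
        assert res.p_value == pytest.approx(float(Fraction(66, 252)), rel=1e-12)
        assert enumerate_upper_tail(10, 4, 5, 3) == Fraction(66, 252)

    def test_certain_event_p_one(self):
        coll = collection_for(6, 6)
        (res,) = hypergeom_ora({f"G{i}" for i in range(6)}, coll)
        assert res.p_value == pytest.approx(1.0)

    def test_enrichment_ratio_arithmetic(self):
        """N=100, K=10, n=20, k=6 -> e=2, R=3."""
        coll = collection_for(100, 10)
        study = {f"G{i}" for i in range(6)} | {f"G{i}" for i in range(50, 64)}
        (res,) = hypergeom_ora(study, coll)
        assert res.overlap == 6
        assert res.expected == pytest.approx(2.0)
        assert res.enrichment_ratio == pytest.approx(3.0)

    def test_zero_overlap_reported_with_p_one(self):
        coll = collection_for(20, 5)
        (res,) = hypergeom_ora({f"G{i}" for i in range(10, 15)}, coll)
        assert res.overlap == 0 and res.p_value == 1.0 and res.enrichment_ratio == 0.0

    def test_genes_outside_universe_dropped(self):
        coll = collection_for(10, 4)
        (res,) = hypergeom_ora({"G0", "G1", "NOTTHERE"}, coll)
        assert res.study_size == 2

    def test_empty_study_after_intersection_errors(self):
        with pytest.raises(ValueError):
            hypergeom_ora({"ZZZ"}, collection_for(10, 4))

    def test_matches_enumeration_on_random_small_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(60):
            n_univ = int(rng.integers(3, 13))
            n_set = int(rng.integers(1, n_univ + 1))
            n_study = int(rng.integers(1, n_univ + 1))
            study = {f"G{i}" for i in rng.choice(n_univ, size=n_study, replace=False)}
            coll = collection_for(n_univ, n_set)
            (res,) = hypergeom_ora(study, coll)
            k = res.overlap
            if k == 0:
                assert res.p_value == 1.0
                continue
            expected = enumerate_upper_tail(n_univ, n_set, n_study, k)
            assert res.p_value == pytest.approx(float(expected), rel=1e-9)


class TestBhFdr:
    def test_step_up_worked_example(self):
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=20), st.randoms())
    @settings(derandomize=True, max_examples=50)
    def test_permutation_invariance_and_bounds(self, ps, rnd):
        base = bh_fdr(ps)
        idx = list(range(len(ps)))
        rnd.shuffle(idx)
        shuffled = bh_fdr([ps[i] for i in idx])
        assert [shuffled[idx.index(j)] for j in range(len(ps))] == pytest.approx(base)
        assert all(0.0 <= q <= 1.0 for q in base)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(7)
        for _ in range(20):
            ps = rng.uniform(size=int(rng.integers(1, 30)))
            ref = multipletests(ps, method="fdr_bh")[1]
            assert bh_fdr(ps.tolist()) == pytest.approx(ref.tolist())


def make_result(name, genes, q):
    return EnrichmentResult(
        name=name,
        overlap=len(genes),
        set_size=len(genes),
        study_size=50,
        universe_size=500,
        p_value=q / 2,
        q_value=q,
        overlap_genes=frozenset(genes),
    )


class TestWeightedSetCover:
    def test_disjoint_sets_both_selected_by_weighted_gain(self):
        a = make_result("A", {"g1", "g2", "g3"}, 1e-4)
        b = make_result("B", {"g4", "g5"}, 1e-2)
        sel = weighted_set_cover([a, b], max_sets=2)
        assert sel.selected == ["A", "B"]
        assert sel.coverage_fraction == pytest.approx(1.0)

    def test_subset_contributes_nothing_and_is_skipped(self):
        big = make_result("A", {"g1", "g2", "g3"}, 1e-3)
        small = make_result("B", {"g1", "g2"}, 1e-3)
        sel = weighted_set_cover([big, small], max_sets=5)
        assert sel.selected == ["A"]

    def test_greedy_within_guarantee_of_optimal_two_cover(self):
        """Greedy 2-set coverage >= (1 - 1/e) x best exhaustive 2-set cover."""
        rng = np.random.default_rng(3)
        genes = [f"g{i}" for i in range(30)]
        for trial in range(20):
            results = [
                make_result(
                    f"S{j}",
                    set(rng.choice(genes, size=int(rng.integers(3, 12)), replace=False)),
                    float(10.0 ** -rng.integers(2, 8)),
                )
                for j in range(5)
            ]
            sel = weighted_set_cover(results, max_sets=2)
            best = max(
                len(a.overlap_genes | b.overlap_genes)
                for a, b in combinations(results, 2)
            )
            assert len(sel.covered) >= (1 - 1 / np.e) * best

    def test_empty_input(self):
        sel = weighted_set_cover([])
        assert sel.selected == [] and sel.coverage_fraction == 0.0

    def test_coverage_target_stops_selection(self):
        a = make_result("A", {"g1", "g2", "g3", "g4"}, 1e-6)
        b = make_result("B", {"g5"}, 1e-2)
        sel = weighted_set_cover([a, b], coverage_target=0.5)
        assert sel.selected == ["A"]


class TestReport:
    def test_sorted_by_q_then_p_then_name(self):
        rows = [make_result(n, {f"x{i}"}, q) for i, (n, q) in
                enumerate([("B", 0.2), ("A", 0.2), ("C", 0.1)])]
        frame = enrichment_report(rows)
        assert frame["name"].tolist() == ["C", "A", "B"]

    def test_empty_table_has_header_only(self):
        frame = enrichment_report([])
        assert len(frame) == 0
        assert "enrichment_ratio" in frame.columns

    def test_significance_filter(self):
        rows = [make_result("A", {"x"}, 0.01), make_result("B", {"y"}, 0.8)]
        assert [r.name for r in significant_results(rows)] == ["A"]
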