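import itertools
import math
import random

import pandas as pd
import pytest
from scipy import stats

from spliceflank.sets import (consensus, filter_de, fisher_overlap,
                              intronless_fraction, read_gene_list,
                              select_sars, term_enrichment, write_gene_list)


def de_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "fold_change",
                                       "significance"])


def rip_table(rows):
    return pd.DataFrame(rows, columns=["gene_id", "line", "fold_change",
                                       "significance"])


class TestFilterDe:
    def test_threshold_boundaries(self):
        table = de_table([
            ("up_exact", 2.0, 0.09),     # fold cut is inclusive -> up
            ("up_clear", 3.5, 0.001),
            ("fold_short", 1.9, 0.001),  # below fold cut -> neither
            ("sig_exact", 4.0, 0.1),     # significance cut is strict -> out
            ("down_exact", 0.5, 0.05),   # 1/min_fc, inclusive -> down
            ("down_clear", 0.2, 0.05),
            ("down_short", 0.6, 0.05),
        ])
        up, down = filter_de(table)
        assert up == {"up_exact", "up_clear"}
        assert down == {"down_exact", "down_clear"}

    def test_custom_thresholds(self):
        table = de_table([("g", 1.5, 0.04)])
        assert filter_de(table, min_fc=1.5, max_sig=0.05) == ({"g"}, set())
        assert filter_de(table, min_fc=1.5, max_sig=0.04) == (set(), set())

    def test_non_positive_fold_change_warns_and_drops(self):
        table = de_table([("ok", 2.5, 0.01), ("bad", -1.0, 0.01),
                          ("zero", 0.0, 0.01)])
        with pytest.warns(UserWarning, match="non-positive"):
            up, down = filter_de(table)
        assert up == {"ok"} and down == set()

    def test_fold_inversion_swaps_directions(self):
        random.seed(0)
        rows = [(f"g{i}", math.exp(random.uniform(-2, 2)),
                 random.uniform(0, 0.2)) for i in range(200)]
        up, down = filter_de(de_table(rows))
        inv = de_table([(g, 1.0 / fc, sig) for g, fc, sig in rows])
        up_inv, down_inv = filter_de(inv)
        assert (up, down) == (down_inv, up_inv)


class TestConsensus:
    def test_direction_wise_intersection(self):
        pairs = [
            ({"a", "b", "c"}, {"x", "y"}),
            ({"b", "c", "d"}, {"y", "z"}),
            ({"c", "b"}, {"y"}),
        ]
        assert consensus(pairs) == ({"b", "c"}, {"y"})

    def test_monotone_in_number_of_sources(self):
        random.seed(1)
        pool = [f"g{i}" for i in range(60)]
        pairs = [(set(random.sample(pool, 30)), set(random.sample(pool, 30)))
                 for _ in range(4)]
        up3, down3 = consensus(pairs[:3])
        up4, down4 = consensus(pairs)
        assert up4 <= up3 and down4 <= down3

    def test_requires_two_sources(self):
        with pytest.raises(ValueError, match="two sources"):
            consensus([({"a"}, {"b"})])


class TestSelectSars:
    def test_both_lines_required_per_method(self):
        t = rip_table([
            ("g_both", "line1", 3.0, 0.01), ("g_both", "line2", 2.5, 0.02),
            ("g_one", "line1", 3.0, 0.01),
            ("g_weak", "line1", 3.0, 0.01), ("g_weak", "line2", 1.5, 0.01),
            ("g_insig", "line1", 3.0, 0.01), ("g_insig", "line2", 3.0, 0.2),
        ])
        res = select_sars({"m1": t})
        assert res.genes == frozenset({"g_both"})
        assert res.provenance["per_method_sizes"] == {"m1": 1}

    def test_intersection_across_methods(self):
        t1 = rip_table([
            ("a", "line1", 3.0, 0.01), ("a", "line2", 3.0, 0.01),
            ("b", "line1", 3.0, 0.01), ("b", "line2", 3.0, 0.01),
        ])
        t2 = rip_table([
            ("b", "line1", 3.0, 0.01), ("b", "line2", 3.0, 0.01),
            ("c", "line1", 3.0, 0.01), ("c", "line2", 3.0, 0.01),
        ])
        res = select_sars({"m1": t1, "m2": t2})
        assert res.genes == frozenset({"b"})
        assert res.provenance["per_method_sizes"] == {"m1": 2, "m2": 2}

    def test_fold_boundary_inclusive(self):
        t = rip_table([("g", "line1", 2.0, 0.05), ("g", "line2", 2.0, 0.05)])
        assert select_sars({"m": t}).genes == frozenset({"g"})

    def test_empty_input(self):
        assert select_sars({}).genes == frozenset()


class TestFisherOverlap:
    universe = {f"g{i}" for i in range(100)}

    def test_symmetric_in_arguments(self):
        a = {f"g{i}" for i in range(0, 30)}
        b = {f"g{i}" for i in range(20, 60)}
        odds_ab, p_ab = fisher_overlap(a, b, self.universe)
        odds_ba, p_ba = fisher_overlap(b, a, self.universe)
        assert odds_ab == pytest.approx(odds_ba)
        assert p_ab == pytest.approx(p_ba)

    def test_identical_sets_highly_significant(self):
        a = {f"g{i}" for i in range(20)}
        odds, p = fisher_overlap(a, a, self.universe)
        assert p < 1e-3
        assert math.isinf(odds)

    def test_empty_set_uninformative(self):
        _, p = fisher_overlap(set(), {"g1", "g2"}, self.universe)
        assert p == pytest.approx(1.0)

    def test_genes_outside_universe_ignored(self):
        a = {"g0", "g1", "not_in_universe"}
        b = {"g0", "g1"}
        assert fisher_overlap(a, b, self.universe) == \
            fisher_overlap({"g0", "g1"}, b, self.universe)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            fisher_overlap({"a"}, {"b"}, set())

    def test_matches_enumeration_oracle(self):
        """Two-sided Fisher p equals the sum of hypergeometric point
        probabilities no larger than the observed one, enumerated by brute
        force over every possible overlap size (|U| <= 30)."""
        random.seed(2)
        for trial in range(10):
            N = random.randint(8, 30)
            universe = {f"g{i}" for i in range(N)}
            a = set(random.sample(sorted(universe), random.randint(0, N)))
            b = set(random.sample(sorted(universe), random.randint(0, N)))
            k, K, n = len(a & b), len(a), len(b)
            probs = [stats.hypergeom.pmf(x, N, K, n)
                     for x in range(max(0, K + n - N), min(K, n) + 1)]
            obs = stats.hypergeom.pmf(k, N, K, n)
            expected_p = sum(q for q in probs if q <= obs * (1 + 1e-9))
            _, p = fisher_overlap(a, b, universe)
            assert p == pytest.approx(min(1.0, expected_p), rel=1e-9)


class TestTermEnrichment:
    def test_fold_arithmetic(self):
        # universe 100, term covers 10, query 20, 8 hits:
        # expected = 20*10/100 = 2, fold = 4
        universe = {f"g{i}" for i in range(100)}
        term_map = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(10)],
            "term": ["defense"] * 10,
        })
        query = {f"g{i}" for i in range(8)} | {f"g{i}" for i in range(50, 62)}
        table = term_enrichment(query, term_map, universe)
        row = table.iloc[0]
        assert row["actual"] == 8
        assert row["expected"] == pytest.approx(2.0)
        assert row["fold"] == pytest.approx(4.0)
        assert row["p_value"] == pytest.approx(
            stats.hypergeom.sf(7, 100, 10, 20))

    def test_query_equals_universe_unit_fold(self):
        universe = {f"g{i}" for i in range(40)}
        term_map = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(12)], "term": ["t"] * 12,
        })
        table = term_enrichment(universe, term_map, universe)
        assert table.iloc[0]["fold"] == pytest.approx(1.0)
        assert table.iloc[0]["p_value"] == pytest.approx(1.0)

    def test_tail_matches_enumeration(self):
        # U=30, K=6, n=10, k=4: p = sum_{x>=4} C(6,x)C(24,10-x)/C(30,10)
        expected = sum(
            math.comb(6, x) * math.comb(24, 10 - x) for x in range(4, 7)
        ) / math.comb(30, 10)
        universe = {f"g{i}" for i in range(30)}
        term_map = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(6)], "term": ["t"] * 6,
        })
        query = {"g0", "g1", "g2", "g3"} | {f"g{i}" for i in range(20, 26)}
        table = term_enrichment(query, term_map, universe)
        assert table.iloc[0]["p_value"] == pytest.approx(expected)

    def test_terms_outside_universe_skipped(self):
        universe = {"g1", "g2"}
        term_map = pd.DataFrame({
            "gene_id": ["x1", "x2"], "term": ["alien", "alien"],
        })
        assert len(term_enrichment({"g1"}, term_map, universe)) == 0

    def test_sorted_by_p_value(self):
        universe = {f"g{i}" for i in range(50)}
        term_map = pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(8)] + ["g40", "g41", "g42"],
            "term": ["hit"] * 8 + ["miss"] * 3,
        })
        table = term_enrichment({f"g{i}" for i in range(8)}, term_map,
                                universe)
        assert list(table["term"]) == ["hit", "miss"]
        assert table["p_value"].is_monotonic_increasing


class TestIntronlessFraction:
    def test_percentage(self):
        genes = {f"g{i}" for i in range(50)}
        intronless = {"g0", "g1"} | {"other"}
        assert intronless_fraction(genes, intronless) == pytest.approx(4.0)

    def test_no_overlap_zero(self):
        assert intronless_fraction({"a"}, {"b"}) == 0.0

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            intronless_fraction(set(), {"a"})


def test_gene_list_round_trip(tmp_path):
    genes = {"AT1G01010", "AT2G14610", "AT5G64905"}
    path = str(tmp_path / "genes.txt")
    write_gene_list(genes, path)
    assert read_gene_list(path) == genes
    # file is sorted, one gene per line
    lines = (tmp_path / "genes.txt").read_text().splitlines()
    assert lines == sorted(genes)
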