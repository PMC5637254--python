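import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from spliceflank.motifs import (IUPAC, MotifPattern, chisq_motif_test,
                                count_motif, density_per_kb, enrichment_ratio,
                                kmer_overrepresentation,
                                motif_enrichment_table, positional_profile,
                                wbox_scan)
from spliceflank.regions import FlankRegion

_IUPAC_SETS = {
    "A": {"A"}, "C": {"C"}, "G": {"G"}, "T": {"T"},
    "R": {"A", "G"}, "Y": {"C", "T"}, "S": {"C", "G"}, "W": {"A", "T"},
    "K": {"G", "T"}, "M": {"A", "C"}, "B": {"C", "G", "T"},
    "D": {"A", "G", "T"}, "H": {"A", "C", "T"}, "V": {"A", "C", "G"},
    "N": {"A", "C", "G", "T"},
}


def brute_force_count(seq: str, pattern: str) -> int:
    """Position-by-position scanning oracle (N in the sequence matches
    nothing)."""
    seq, pattern = seq.upper(), pattern.upper()
    m = len(pattern)
    hits = 0
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in _IUPAC_SETS[pattern[j]] for j in range(m)):
            hits += 1
    return hits


class TestCountMotif:
    @pytest.mark.parametrize("seq,motif,expected", [
        ("GGAGG", "GGNGG", 1),
        ("GGGGGGG", "GGNGG", 3),     # overlapping starts 0, 1, 2
        ("ACGTACGT", "GGNGG", 0),
        ("GG", "GGNGG", 0),          # motif longer than sequence
        ("GGNGG", "GGNGG", 0),       # N in the sequence matches nothing
        ("ggagg", "GGNGG", 1),       # case-insensitive scan
    ])
    def test_examples(self, seq, motif, expected):
        assert count_motif(seq, motif) == expected

    @settings(max_examples=1000, derandomize=True, deadline=None)
    @given(
        seq=st.text(alphabet="ACGTN", min_size=0, max_size=60),
        motif=st.text(alphabet="ACGTNRYSW", min_size=2, max_size=10),
    )
    def test_matches_brute_force_oracle(self, seq, motif):
        assert count_motif(seq, motif) == brute_force_count(seq, motif)

    def test_nested_motif_inequality(self):
        # every disjoint GGNGGNGG instance contains two GGNGG instances
        rng = np.random.default_rng(0)
        for _ in range(20):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            long_hits = count_motif(seq, "GGNGGNGG")
            # greedy disjoint count
            from spliceflank.motifs import occurrence_starts
            disjoint, last_end = 0, -1
            for s in occurrence_starts(seq, "GGNGGNGG"):
                if s > last_end:
                    disjoint += 1
                    last_end = s + 7
            assert count_motif(seq, "GGNGG") >= 2 * disjoint
            assert long_hits >= disjoint

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            MotifPattern("bad", "GGXGG")
        with pytest.raises(ValueError):
            MotifPattern("short", "G")


class TestDensityEnrichment:
    @pytest.mark.parametrize("count,length,expected", [
        (5, 1000, 5.0),
        (0, 1000, 0.0),
        (3, 700, 3 / 700 * 1000),
    ])
    def test_density(self, count, length, expected):
        assert density_per_kb(count, length) == pytest.approx(expected)

    def test_zero_length_flagged(self):
        with pytest.raises(ValueError):
            density_per_kb(0, 0)

    def test_equal_densities_give_unit_enrichment(self):
        assert enrichment_ratio(2.5, 2.5) == pytest.approx(1.0)

    def test_zero_background_flagged(self):
        with pytest.raises(ValueError):
            enrichment_ratio(1.0, 0.0)

    def test_concatenation_density_is_length_weighted_mean(self):
        rng = np.random.default_rng(1)
        a = "".join(rng.choice(list("ACGT"), size=700))
        b = "".join(rng.choice(list("ACGT"), size=1300))
        ca, cb = count_motif(a, "GGNGG"), count_motif(b, "GGNGG")
        da = density_per_kb(ca, len(a))
        db = density_per_kb(cb, len(b))
        weighted = (da * len(a) + db * len(b)) / (len(a) + len(b))
        assert density_per_kb(ca + cb, len(a) + len(b)) == \
            pytest.approx(weighted)


class TestChiSquared:
    def test_equal_proportions_zero_statistic(self):
        stat, p, degen = chisq_motif_test(10, 1000, 100, 10000)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert not degen

    def test_textbook_value(self):
        # independent hand computation of sum (O-E)^2/E on the 2x2 table
        a, b, c, d = 20, 980, 10, 9990
        n = a + b + c + d
        expected_stat = 0.0
        for obs, row, col in [(a, a + b, a + c), (b, a + b, b + d),
                              (c, c + d, a + c), (d, c + d, b + d)]:
            e = row * col / n
            expected_stat += (obs - e) ** 2 / e
        stat, p, _ = chisq_motif_test(20, 1000, 10, 10000)
        assert stat == pytest.approx(expected_stat)
        assert p == pytest.approx(stats.chi2.sf(expected_stat, 1))

    def test_doubling_counts_doubles_statistic(self):
        s1, p1, _ = chisq_motif_test(20, 1000, 10, 10000)
        s2, p2, _ = chisq_motif_test(40, 2000, 20, 20000)
        assert s2 == pytest.approx(2 * s1)
        assert p2 < p1

    def test_degenerate_table(self):
        assert chisq_motif_test(0, 1000, 0, 10000) == (0.0, 1.0, True)
        assert chisq_motif_test(0, 0, 5, 100) == (0.0, 1.0, True)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            chisq_motif_test(10, 5, 0, 100)


def _regions_with_seqs(seqs, label="ASE", etype="RI", start_id=0):
    out = []
    for i, s in enumerate(seqs):
        out.append(FlankRegion(f"e{start_id + i}", etype, label, "chr1", "+",
                               (start_id + i) * 10000,
                               (start_id + i) * 10000 + len(s), sequence=s))
    return out


class TestEnrichmentTable:
    def test_stratum_identical_to_background(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list("ACGT"), size=400))
                for _ in range(30)]
        regs = _regions_with_seqs(seqs)
        table = motif_enrichment_table({"pos": regs}, regs, ["GGNGG"])
        row = table.iloc[0]
        assert row["enrichment"] == pytest.approx(1.0)
        assert row["p_value"] == pytest.approx(1.0)

    def test_absent_motif_degenerate(self):
        regs = _regions_with_seqs(["ATATATATAT" * 10] * 5)
        table = motif_enrichment_table({"pos": regs}, regs, ["GGNGG"])
        row = table.iloc[0]
        assert row["count"] == 0 and row["density_per_kb"] == 0.0
        assert row["degenerate"]

    def test_rows_per_motif_region_stratum(self):
        regs = _regions_with_seqs(["ACGT" * 100] * 3)
        table = motif_enrichment_table(
            {"pos": regs, "neg": regs}, regs, ["GGNGG", "CGNCGNCG"])
        assert len(table) == 2 * 2  # strata x motifs, one region class
        assert set(table["stratum"]) == {"pos", "neg"}


class TestPositionalProfile:
    def test_single_occurrence(self):
        prof = positional_profile([("AAAAAAAGGAGGAA", 0)], ["GGNGG"])
        assert list(prof["offset"]) == [7]
        assert prof.iloc[0]["fraction"] == pytest.approx(1.0)

    def test_two_motifs_share_an_offset(self):
        # at offset 0 both motifs start once
        prof = positional_profile(
            [("GGAGGAGG", 0)], ["GGNGG", "GGNGGNGG"])
        at0 = prof[prof["offset"] == 0]
        assert sorted(at0["fraction"]) == [0.5, 0.5]

    def test_fractions_sum_to_one_at_each_offset(self):
        rng = np.random.default_rng(3)
        seqs = [("".join(rng.choice(list("ACGT"), size=200)), 100)
                for _ in range(20)]
        prof = positional_profile(seqs, ["GGNGG", "CNCCNNCNCC", "CGNCGNCG"])
        if len(prof):
            sums = prof.groupby("offset")["fraction"].sum()
            assert np.allclose(sums.values, 1.0)

    def test_anchor_offsets(self):
        prof = positional_profile([("GGAGGAAA", 5)], ["GGNGG"])
        assert list(prof["offset"]) == [-5]

    def test_no_occurrences_empty(self):
        assert len(positional_profile([("AAAA", 0)], ["GGNGG"])) == 0


class TestKmerOverrepresentation:
    def test_test_equal_background_not_significant(self):
        rng = np.random.default_rng(4)
        seqs = ["".join(rng.choice(list("ACGT"), size=300))
                for _ in range(10)]
        table = kmer_overrepresentation(seqs, seqs, k=4)
        assert (table["p_value"] >= 0.4999).all()

    def test_planted_kmer_ranks_first(self):
        rng = np.random.default_rng(5)
        bg = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(20)]
        test = []
        for _ in range(20):
            s = list(rng.choice(list("ACGT"), size=300))
            for pos in range(0, 280, 30):   # ~10 planted copies per sequence
                s[pos:pos + 6] = list("GGAGGA")
            test.append("".join(s))
        table = kmer_overrepresentation(test, bg, k=6)
        assert table.iloc[0]["kmer"] == "GGAGGA"

    def test_unseen_background_kmer_gets_pseudocount(self):
        table = kmer_overrepresentation(["GGGGGG"], ["AAAAAAAA"], k=6)
        assert len(table) == 1
        assert 0 < table.iloc[0]["p_value"] <= 1

    def test_empty_inputs(self):
        assert len(kmer_overrepresentation([], ["ACGT"], k=2)) == 0


class TestWboxScan:
    def test_presence_flags(self):
        presence, _ = wbox_scan(
            {"g1": "AAATTGACCAAA", "g2": "A" * 20},
            {"TTTGAC": 1e-4, "TTGACC": 1e-4, "TTGACT": 1e-4},
        )
        row1 = presence.set_index("gene_id").loc["g1"]
        row2 = presence.set_index("gene_id").loc["g2"]
        assert bool(row1["TTGACC"]) and not bool(row1["TTTGAC"])
        assert not row2[["TTTGAC", "TTGACC", "TTGACT"]].any()

    def test_binomial_tail_matches_oracle(self):
        # 100 genes, each upstream sequence carrying exactly one TTTGAC
        seqs = {f"g{i}": ("A" * 200 + "TTTGAC" + "A" * 294)
                for i in range(100)}
        _, summary = wbox_scan(seqs, {"TTTGAC": 1e-4}, motifs=("TTTGAC",))
        row = summary.iloc[0]
        n = 100 * (500 - 6 + 1)
        assert row["occurrences"] == 100 and row["scan_positions"] == n
        expected = stats.binom.sf(99, n, 1e-4)
        assert row["p_value"] == pytest.approx(expected)

    def test_sequence_shorter_than_motif(self):
        presence, summary = wbox_scan({"g": "TTG"}, {"TTGACC": 1e-4},
                                      motifs=("TTGACC",))
        assert not presence.iloc[0]["TTGACC"]
        assert summary.iloc[0]["p_value"] == 1.0
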