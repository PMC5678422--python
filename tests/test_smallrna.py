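"""Small RNA filtering, hierarchical exclusion and the duplex signature."""

import numpy as np
import pandas as pd
import pytest

from tetrap.smallrna import (
    assign_te_class, class_rpm, consensus_profile, filter_by_length,
    five_prime_composition, hierarchical_exclusion, length_strand_distribution,
    overlap_signature, te_class_smallrna,
)


def _reads(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "strand"])
    df["length"] = df["end"] - df["start"]
    return df


def brute_force_signature(reads, max_overlap=30):
    """Exhaustive pair enumeration oracle for the 5'-5' overlap counts."""
    counts = {o: 0 for o in range(1, max_overlap + 1)}
    plus = reads[reads["strand"] == "+"]
    minus = reads[reads["strand"] == "-"]
    for p in plus.itertuples(index=False):
        for m in minus.itertuples(index=False):
            if p.chrom != m.chrom:
                continue
            if not (p.start < m.end and m.start < p.end):
                continue
            o = (m.end - 1) - p.start + 1
            if 1 <= o <= max_overlap:
                counts[o] += 1
    return counts


class TestLengthFilter:
    def test_inclusive_bounds(self):
        df = pd.DataFrame({"length": [19, 20, 22, 24, 25]})
        kept = filter_by_length(df)
        assert kept["length"].tolist() == [20, 22, 24]

    def test_empty_input(self):
        assert len(filter_by_length(pd.DataFrame({"length": []}))) == 0

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            filter_by_length(pd.DataFrame({"length": [22]}), min_nt=24, max_nt=20)

    def test_survivor_count_matches_hand_count(self):
        lengths = [18, 20, 21, 21, 23, 24, 24, 25, 30, 22]
        kept = filter_by_length(pd.DataFrame({"length": lengths}))
        assert len(kept) == sum(20 <= l <= 24 for l in lengths)


class TestHierarchicalExclusion:
    RRNA = pd.DataFrame([("chr1", 0, 100)], columns=["chrom", "start", "end"])
    MIRNA = pd.DataFrame([("chr1", 50, 200)], columns=["chrom", "start", "end"])
    REPEATS = pd.DataFrame([("chr1", 300, 400)], columns=["chrom", "start", "end"])

    def test_rule_order_rrna_wins(self):
        reads = _reads([("chr1", 60, 82, "+")])  # overlaps both rRNA and miRNA
        out = hierarchical_exclusion(reads, self.RRNA, self.MIRNA, self.REPEATS)
        assert out.loc[0, "bin"] == "rRNA"

    def test_unannotated_read_is_genome(self):
        reads = _reads([("chr1", 500, 522, "+")])
        out = hierarchical_exclusion(reads, self.RRNA, self.MIRNA, self.REPEATS)
        assert out.loc[0, "bin"] == "genome"

    def test_repeat_read_in_final_bin(self):
        reads = _reads([("chr1", 350, 372, "-")])
        out = hierarchical_exclusion(reads, self.RRNA, self.MIRNA, self.REPEATS)
        assert out.loc[0, "bin"] == "repeat"

    def test_partition_matches_brute_force(self):
        rng = np.random.default_rng(9)
        rows = [("chr1", int(s), int(s) + 22, "+") for s in rng.integers(0, 600, 30)]
        reads = _reads(rows)
        out = hierarchical_exclusion(reads, self.RRNA, self.MIRNA, self.REPEATS)

        def expected_bin(s, e):
            if s < 100 and e > 0:
                return "rRNA"
            if s < 200 and e > 50:
                return "miRNA"
            if s < 400 and e > 300:
                return "repeat"
            return "genome"

        manual = [expected_bin(r.start, r.end) for r in reads.itertuples(index=False)]
        assert out["bin"].tolist() == manual

    def test_partition_is_exhaustive_and_idempotent(self):
        rng = np.random.default_rng(4)
        rows = [("chr1", int(s), int(s) + 21, "-") for s in rng.integers(0, 600, 50)]
        reads = _reads(rows)
        out = hierarchical_exclusion(reads, self.RRNA, self.MIRNA, self.REPEATS)
        assert len(out) == len(reads)
        again = hierarchical_exclusion(out, self.RRNA, self.MIRNA, self.REPEATS)
        assert out["bin"].tolist() == again["bin"].tolist()


class TestLengthStrand:
    def test_single_cell(self):
        reads = _reads([("c", 0, 22, "+"), ("c", 5, 27, "+")])
        dist = length_strand_distribution(reads)
        assert dist.loc[22, "+"] == 2

    def test_total_conservation_and_strand_marginal(self):
        rng = np.random.default_rng(7)
        rows = [("c", 0, int(l), "+" if rng.random() < 0.5 else "-")
                for l in rng.integers(20, 25, 40)]
        reads = _reads(rows)
        dist = length_strand_distribution(reads)
        assert dist.to_numpy().sum() == 40
        marginal = dist.sum(axis=1)
        plain = reads["length"].value_counts()
        assert marginal.sort_index().tolist() == plain.sort_index().tolist()


class TestFivePrime:
    def test_all_u(self):
        reads = pd.DataFrame({"sequence": ["TAGC", "TTTT", "TCGA"]})
        comp = five_prime_composition(reads)
        assert comp["U"] == 1.0

    def test_toy_tally(self):
        seqs = ["AAA", "CCC", "GGG", "TTT", "TAA", "TCC", "AGG", "TGG"]
        comp = five_prime_composition(pd.DataFrame({"sequence": seqs}))
        assert comp == {"A": 0.25, "C": 0.125, "G": 0.125, "U": 0.5}

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            five_prime_composition(pd.DataFrame({"sequence": []}))


class TestOverlapSignature:
    def test_single_duplex_overlap_twenty(self):
        """A 22-nt guide pair with 2-nt 3' overhangs overlaps at nt 20."""
        x = 1000
        reads = _reads([("c", x, x + 22, "+"), ("c", x - 2, x + 20, "-")])
        sig = overlap_signature(reads)
        assert sig.counts[20] == 1
        assert sig.n_pairs == 1
        assert sig.mode == 20

    def test_same_strand_reads_empty(self):
        reads = _reads([("c", 0, 22, "+"), ("c", 10, 32, "+")])
        sig = overlap_signature(reads)
        assert sig.n_pairs == 0
        assert sig.mode is None

    def test_six_read_toy_matches_brute_force(self):
        reads = _reads([
            ("c", 100, 122, "+"), ("c", 98, 120, "-"),
            ("c", 105, 126, "+"), ("c", 112, 134, "-"),
            ("d", 50, 74, "+"), ("d", 49, 70, "-"),
        ])
        sig = overlap_signature(reads)
        assert sig.counts == brute_force_signature(reads)

    def test_hundred_random_reads_match_brute_force(self):
        rng = np.random.default_rng(12)
        rows = [("c", int(s), int(s + l), "+" if rng.random() < 0.5 else "-")
                for s, l in zip(rng.integers(0, 300, 100), rng.integers(20, 25, 100))]
        reads = _reads(rows)
        sig = overlap_signature(reads)
        assert sig.counts == brute_force_signature(reads)

    def test_zscore_positive_at_enriched_length(self):
        x = 0
        rows = []
        for i in range(30):  # 30 identical duplexes
            rows += [("c", x + 100 * i, x + 100 * i + 22, "+"),
                     ("c", x + 100 * i - 2, x + 100 * i + 20, "-")]
        sig = overlap_signature(_reads(rows))
        assert sig.mode == 20
        assert sig.zscores[20] > 2


class TestConsensusProfile:
    def test_pileup_positions(self):
        reads = pd.DataFrame({"cons_start": [10], "length": [22]})
        cover = consensus_profile(reads, 50)
        assert cover[9] == 0 and cover[10] == 1 and cover[31] == 1 and cover[32] == 0

    def test_coverage_conservation(self):
        rng = np.random.default_rng(5)
        starts = rng.integers(0, 70, 5)
        lengths = rng.integers(20, 25, 5)
        reads = pd.DataFrame({"cons_start": starts, "length": lengths})
        cover = consensus_profile(reads, 100)
        assert cover.sum() == lengths.sum()

    def test_five_read_manual_pileup(self):
        reads = pd.DataFrame({"cons_start": [0, 0, 5, 10, 30], "length": [20, 20, 20, 20, 20]})
        cover = consensus_profile(reads, 60)
        manual = np.zeros(60, dtype=int)
        for s, l in zip(reads["cons_start"], reads["length"]):
            manual[s : s + l] += 1
        np.testing.assert_array_equal(cover, manual)

    def test_out_of_bounds_rejected(self):
        reads = pd.DataFrame({"cons_start": [40], "length": [22]})
        with pytest.raises(ValueError, match="bounds"):
            consensus_profile(reads, 50)


class TestClassDifferential:
    def test_identical_groups_not_significant(self):
        rpm = pd.DataFrame(
            {"a1": [5.0], "a2": [5.0], "b1": [5.0], "b2": [5.0]}, index=["X"]
        )
        res = te_class_smallrna(rpm, ["a1", "a2"], ["b1", "b2"])
        assert not res["significant"].any()

    def test_student_t_matches_hand_formula(self):
        import math
        a = np.array([10.0, 12.0, 11.0])
        b = np.array([30.0, 28.0, 33.0])
        rpm = pd.DataFrame(
            {"a1": [a[0]], "a2": [a[1]], "a3": [a[2]],
             "b1": [b[0]], "b2": [b[1]], "b3": [b[2]]}, index=["X"]
        )
        res = te_class_smallrna(rpm, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        sp2 = ((a.var(ddof=1) * 2) + (b.var(ddof=1) * 2)) / 4  # pooled variance
        t_manual = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 3 + 1 / 3))
        assert res.loc["X", "t"] == pytest.approx(t_manual, abs=1e-9)
        assert res.loc["X", "stars"] in {"*", "**"}

    def test_star_tiers(self):
        rpm = pd.DataFrame(
            {"a1": [1.0], "a2": [1.01], "a3": [0.99],
             "b1": [50.0], "b2": [50.2], "b3": [49.8]}, index=["X"]
        )
        res = te_class_smallrna(rpm, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res.loc["X", "stars"] == "**"


def test_assign_te_class_and_rpm():
    tes = pd.DataFrame(
        [("chr1", 0, 500, "+", "A", "Af", "i1"), ("chr1", 1000, 1500, "+", "B", "Bf", "i2")],
        columns=["chrom", "start", "end", "strand", "te_class", "family", "id"],
    )
    reads = _reads([("chr1", 10, 32, "+"), ("chr1", 1100, 1122, "-"), ("chr1", 700, 722, "+")])
    assigned = assign_te_class(reads, tes)
    assert sorted(assigned["te_class"]) == ["A", "B"]
    rpm = class_rpm({"s": reads}, tes)
    # 1 read of each class out of a 3-read library
    assert rpm.loc["A", "s"] == pytest.approx(1 / 3 * 1e6)
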