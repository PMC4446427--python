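"""Tract scanning, censuses and interval intersection."""

import itertools
import re

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tractvar import (Tract, build_census, census_percent_difference,
                      intersect_fraction, scan_sequence)
from tractvar.tracts import IntervalSet, revcomp

COMP = {"A": "T", "T": "A", "C": "G", "G": "C", "N": "N"}


def brute_force_scan(chrom, seq):
    """Independent maximal-run finder via itertools.groupby."""
    seq = re.sub(r"[^ACGT]", "N", seq.upper())
    out = []
    i = 0
    for base, grp in itertools.groupby(seq):
        length = sum(1 for _ in grp)
        start, end = i, i + length
        i = end
        if base == "N" or not (4 <= length <= 13):
            continue
        if start == 0 or end == len(seq):
            continue
        left, right = seq[start - 1], seq[end]
        if base in "AG":
            out.append((start, end, "A" if base == "A" else "G", "+", left, right))
        else:
            out.append(
                (start, end, "A" if base == "T" else "G", "-", COMP[right], COMP[left])
            )
    return out


def as_tuples(tracts):
    return [
        (t.start, t.end, t.tract_class, t.purine_strand, t.flank5, t.flank3)
        for t in tracts
    ]


class TestScanSequence:
    @pytest.mark.parametrize(
        "seq,expected",
        [
            ("CAAAAT", [(1, 5, "A", "+", "C", "T")]),
            ("ATTTTG", [(1, 5, "A", "-", "C", "T")]),
            ("T" + "G" * 14 + "T", []),  # run longer than 13 is excluded
            ("CAAANAAAT", []),  # N splits the run into two length-3 runs
            ("AAAAT", []),  # no 5' flank: excluded
            ("CAAAA", []),  # no 3' flank: excluded
            ("NAAAAT", [(1, 5, "A", "+", "N", "T")]),  # N flank retained
            ("agCCCCt", [(2, 6, "G", "-", "A", "C")]),  # case-insensitive
        ],
    )
    def test_examples(self, seq, expected):
        assert as_tuples(scan_sequence("c1", seq)) == expected

    def test_empty_sequence(self):
        assert scan_sequence("c1", "") == []

    def test_invalid_identifier(self):
        with pytest.raises(ValueError):
            scan_sequence("", "CAAAAT")

    def test_purine_position_mapping(self):
        plus = scan_sequence("c1", "CAAAAT")[0]
        assert [plus.purine_position(x) for x in range(0, 6)] == [0, 1, 2, 3, 4, 5]
        minus = scan_sequence("c1", "ATTTTG")[0]
        # reverse strand: position counts from the 3' end of the forward run
        assert [minus.purine_position(x) for x in range(5, -1, -1)] == [0, 1, 2, 3, 4, 5]

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=400))
    def test_matches_bruteforce(self, seq):
        assert as_tuples(scan_sequence("c", seq)) == brute_force_scan("c", seq)

    @settings(derandomize=True, max_examples=300, deadline=None)
    @given(st.text(alphabet="ACGTNacgt", min_size=0, max_size=400))
    def test_reverse_complement_invariance(self, seq):
        fwd = scan_sequence("c", seq)
        rev = scan_sequence("c", revcomp(seq))
        L = len(seq)
        mapped = sorted(
            (L - t.end, L - t.start, t.tract_class, t.flank5, t.flank3) for t in rev
        )
        orig = sorted(
            (t.start, t.end, t.tract_class, t.flank5, t.flank3) for t in fwd
        )
        assert mapped == orig

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.text(alphabet="ACGTN", min_size=0, max_size=400))
    def test_tract_invariants(self, seq):
        for t in scan_sequence("c", seq):
            assert 4 <= t.n <= 13 and t.end - t.start == t.n
            assert t.flank5 != t.tract_class and t.flank3 != t.tract_class
            allowed = {"T", "C", "G", "N"} if t.tract_class == "A" else {"T", "C", "A", "N"}
            assert t.flank5 in allowed and t.flank3 in allowed


class TestCensus:
    def tracts(self):
        return scan_sequence("c1", "GCAAAATTTTTCGGGGGTCA")

    def test_counts_without_mask(self):
        census = build_census(self.tracts())
        assert census.total == 3

    def test_mask_whole_containment(self):
        # mask covers only the first tract wholly
        census = build_census(self.tracts(), mask=[("c1", 0, 7)])
        assert census.total == 1
        # partial overlap does not count
        census = build_census(self.tracts(), mask=[("c1", 0, 5)])
        assert census.total == 0

    def test_additivity_over_sequences(self):
        s1, s2 = "GCAAAATG", "TGGGGGA"
        joint = build_census(scan_sequence("a", s1)) + build_census(scan_sequence("b", s2))
        merged = build_census(scan_sequence("a", s1) + scan_sequence("b", s2))
        pd.testing.assert_frame_equal(
            joint.table.sort_values(list(joint.table.columns)).reset_index(drop=True),
            merged.table.sort_values(list(merged.table.columns)).reset_index(drop=True),
        )

    def test_marginal_consistency(self, small_sim):
        census = build_census(small_sim["tracts"])
        marg = census.marginal()
        assert marg["count"].sum() == census.total
        for row in marg.itertuples(index=False):
            assert census.count(row.tract_class, row.n) == row.count


class TestCensusPercentDifference:
    def census_from_counts(self, counts):
        rows = [("A", n, "T", "T", c) for n, c in counts.items()]
        return build_census([]).__class__(
            pd.DataFrame(rows, columns=["tract_class", "n", "flank5", "flank3", "count"])
        )

    def test_identical_censuses_are_zero(self):
        a = self.census_from_counts({4: 100, 5: 50, 9: 10})
        out = census_percent_difference(a, a)
        assert np.allclose(out.percent_difference, 0)

    def test_scale_invariance(self):
        a = self.census_from_counts({4: 100, 5: 50, 9: 10})
        b = self.census_from_counts({4: 50, 5: 25, 9: 5})
        out = census_percent_difference(a, b)
        assert np.allclose(out.percent_difference, 0)

    def test_doubled_stratum_against_hand_computation(self):
        counts_a = {4: 100, 5: 50, 9: 20}
        counts_b = {4: 100, 5: 50, 9: 10}
        a = self.census_from_counts(counts_a)
        b = self.census_from_counts(counts_b)
        out = census_percent_difference(a, b).set_index("n").percent_difference
        tot_a, tot_b = sum(counts_a.values()), sum(counts_b.values())
        for n in counts_a:
            expected = (counts_a[n] / tot_a - counts_b[n] / tot_b) / (counts_b[n] / tot_b) * 100
            assert out[n] == pytest.approx(expected)

    def test_raw_count_option(self):
        a = self.census_from_counts({4: 100})
        b = self.census_from_counts({4: 50})
        out = census_percent_difference(a, b, normalize=False)
        assert out.percent_difference.iloc[0] == pytest.approx(100.0)


class TestIntersectFraction:
    def test_fully_contained_tract(self):
        tracts = scan_sequence("c1", "GCAAAATG")
        out = intersect_fraction(tracts, [("c1", 0, 8)], unit="tract")
        assert out.percent_overlapping.iloc[0] == 100.0

    def test_half_covered_bp(self):
        tracts = scan_sequence("c1", "GCAAAATG")  # tract at [2, 6)
        out = intersect_fraction(tracts, [("c1", 4, 8)], unit="bp")
        assert out.percent_overlapping.iloc[0] == 50.0

    def test_empty_interval_set(self):
        tracts = scan_sequence("c1", "GCAAAATG")
        out = intersect_fraction(tracts, [], unit="tract")
        assert (out.percent_overlapping == 0).all()

    def test_random_against_naive_oracle(self):
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        tracts = scan_sequence("c1", seq)
        ivs = []
        for _ in range(40):
            s = int(rng.integers(0, 4900))
            ivs.append(("c1", s, s + int(rng.integers(1, 100))))
        covered = np.zeros(6000, dtype=bool)
        for _, s, e in ivs:
            covered[s:e] = True
        out = intersect_fraction(tracts, ivs, unit="bp").set_index(["tract_class", "n"])
        num = {}
        den = {}
        for t in tracts:
            key = (t.tract_class, t.n)
            den[key] = den.get(key, 0) + t.n
            num[key] = num.get(key, 0) + int(covered[t.start : t.end].sum())
        for key, d in den.items():
            assert out.loc[key, "percent_overlapping"] == pytest.approx(num[key] / d * 100)


def test_interval_set_merges_overlaps():
    ivs = IntervalSet([("c", 0, 10), ("c", 5, 15), ("c", 20, 25)])
    assert ivs.overlap_bp("c", 0, 30) == 20
    assert ivs.contains("c", 2, 14)
    assert not ivs.contains("c", 14, 21)
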