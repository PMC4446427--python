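"""Variant normalization and tract assignment."""

import itertools

import numpy as np
import pytest

from tractvar import (Tract, VariantRecord, assign_indel, assign_snv,
                      dedupe_variants, map_variants, normalize_variants,
                      scan_sequence)
from tractvar.tracts import revcomp


class TestNormalize:
    def test_homopolymer_deletion_left_aligned(self):
        ref = {"c1": "ATTTTG"}
        out = normalize_variants([("c1", 4, "TT", "T")], ref)
        assert out == [VariantRecord("c1", 1, "AT", "A")]

    def test_non_variant_dropped(self):
        ref = {"c1": "ATTTTG"}
        assert normalize_variants([("c1", 5, "T", "T")], ref) == []

    def test_multiallelic_split(self):
        ref = {"c1": "ACG"}
        out = normalize_variants([("c1", 2, "C", ["A", "T"])], ref)
        assert out == [VariantRecord("c1", 2, "C", "A"), VariantRecord("c1", 2, "C", "T")]

    def test_ref_mismatch_dropped(self, caplog):
        ref = {"c1": "ACG"}
        assert normalize_variants([("c1", 2, "G", "A")], ref) == []

    def test_missing_contig_raises(self):
        with pytest.raises(KeyError, match="c9"):
            normalize_variants([("c9", 1, "A", "T")], {"c1": "ACGT"})

    def test_insertion_left_aligned(self):
        # +T inside a T-run shifts to the run's leftmost placement
        ref = {"c1": "GATTTTC"}
        out = normalize_variants([("c1", 5, "T", "TT")], ref)
        assert out == [VariantRecord("c1", 2, "A", "AT")]

    def test_shared_prefix_suffix_trimmed(self):
        ref = {"c1": "GACTT"}
        out = normalize_variants([("c1", 2, "ACT", "AGT")], ref)
        assert out == [VariantRecord("c1", 3, "C", "G")]


def test_dedupe_unique_sorted_and_shuffle_invariant():
    recs = [
        VariantRecord("c1", 5, "A", "T"),
        VariantRecord("c1", 5, "A", "T"),
        VariantRecord("c1", 5, "A", "C"),
        VariantRecord("c1", 2, "G", "C"),
    ]
    out = dedupe_variants(recs)
    assert out == [
        VariantRecord("c1", 2, "G", "C"),
        VariantRecord("c1", 5, "A", "C"),
        VariantRecord("c1", 5, "A", "T"),
    ]
    assert dedupe_variants(reversed(recs)) == out


class TestAssignSNV:
    def test_plus_strand_interior(self):
        t = Tract("c1", 10, 14, "A", "+", "C", "T")
        a = assign_snv(t, VariantRecord("c1", 11, "A", "T"))
        assert (a.category, a.position, a.substitution) == ("tract_SNV", 1, ("A", "T"))

    def test_minus_strand_complementation(self):
        t = Tract("c1", 20, 25, "G", "-", "T", "T")
        a = assign_snv(t, VariantRecord("c1", 23, "C", "A"))
        assert (a.category, a.position, a.substitution) == ("tract_SNV", 3, ("G", "T"))

    def test_flank_snv_extends_tract(self):
        t = Tract("c1", 10, 14, "A", "+", "C", "T")
        a = assign_snv(t, VariantRecord("c1", 10, "C", "A"))
        assert (a.category, a.position) == ("flank_SNV", 0)
        assert a.substitution == ("C", "A") and a.extends_tract

    def test_outside_returns_none(self):
        t = Tract("c1", 10, 14, "A", "+", "C", "T")
        assert assign_snv(t, VariantRecord("c1", 8, "G", "A")) is None
        assert assign_snv(t, VariantRecord("c1", 16, "G", "A")) is None

    def test_cpg_context_flag(self):
        t = Tract("c1", 10, 14, "G", "+", "C", "T")
        a = assign_snv(t, VariantRecord("c1", 11, "G", "A"))
        assert a.cpg_context


def edited_sequence(seq, v):
    """Independent application of a normalized edit to a sequence string."""
    a0 = v.pos - 1
    if v.vtype == "INS":
        return seq[: a0 + 1] + v.alt[1:] + seq[a0 + 1 :]
    if v.vtype == "DEL":
        return seq[: a0 + 1] + seq[a0 + 1 + v.size :]
    return seq[:a0] + v.alt + seq[a0 + 1 :]


def runs_of(seq):
    out = []
    i = 0
    for base, grp in itertools.groupby(seq):
        L = sum(1 for _ in grp)
        out.append((i, i + L, base))
        i += L
    return out


class TestAssignIndel:
    SEQ = "GGTCAAAAATGGC"  # A-tract n=5 at [4, 9)

    def tract(self):
        (t,) = scan_sequence("c1", self.SEQ)
        return t

    def test_one_base_deletion_is_slippage_minus(self):
        ref = {"c1": self.SEQ}
        v = VariantRecord("c1", 4, "CA", "C")
        a = assign_indel(self.tract(), v, ref)
        assert a.category == "slippage_minus" and a.location == "in_tract"

    def test_run_base_insertion_is_slippage_plus_with_junction(self):
        ref = {"c1": self.SEQ}
        v = VariantRecord("c1", 6, "A", "AA")  # as-reported junction j=2
        a = assign_indel(self.tract(), v, ref)
        assert (a.category, a.position) == ("slippage_plus", 2)

    def test_non_run_base_insertion_splits_run(self):
        ref = {"c1": self.SEQ}
        v = VariantRecord("c1", 6, "A", "AG")
        a = assign_indel(self.tract(), v, ref)
        assert (a.category, a.position) == ("indel_ins", 2)
        # apply-and-rescan oracle: the containing run is no longer length 6
        runs = runs_of(edited_sequence(self.SEQ, v))
        assert not any(b == "A" and e - s == 6 for s, e, b in runs)

    def test_flank_deletion_is_before_tract(self):
        ref = {"c1": self.SEQ}
        v = VariantRecord("c1", 3, "TC", "T")  # deletes the 5' flank C
        a = assign_indel(self.tract(), v, ref)
        assert (a.category, a.location) == ("indel_del", "before_tract")

    def test_distant_indel_returns_none(self):
        ref = {"c1": self.SEQ + "T" * 20}
        v = VariantRecord("c1", 12, "GC", "G")
        assert assign_indel(self.tract(), v, ref) is None

    def test_minus_strand_locations_mirror(self):
        seq = "GGCTTTTTGACC"  # T-run: purine strand '-'
        (t,) = scan_sequence("c1", seq)
        assert t.purine_strand == "-"
        ref = {"c1": seq}
        # deleting the forward-left flank base (coord 2, 'C') touches the
        # purine-strand 3' side of the tract
        a = assign_indel(t, VariantRecord("c1", 2, "GC", "G"), ref)
        assert (a.category, a.location) == ("indel_del", "after_tract")

    def test_oversized_indel_ignored(self):
        ref = {"c1": "GG" + "T" * 300 + self.SEQ}
        v = VariantRecord("c1", 302, "C" + "T" * 201, "C")
        t = Tract("c1", 306, 311, "A", "+", "C", "T")
        assert assign_indel(t, v, ref) is None


class TestSlippageRoundTrip:
    def test_random_cases_rescan_consistently(self):
        """Every slippage call, applied and re-run-length-measured by an
        independent routine, yields n±1 with both flank identities kept."""
        rng = np.random.default_rng(42)
        checked = 0
        for _ in range(60):
            seq = "".join(rng.choice(list("ACGT"), size=800, p=[0.3, 0.2, 0.2, 0.3]))
            tracts = scan_sequence("c1", seq)
            ref = {"c1": seq}
            for t in tracts:
                for _ in range(4):
                    a0 = int(rng.integers(max(1, t.start - 2), min(len(seq) - 2, t.end + 1)))
                    if rng.random() < 0.5:
                        v = VariantRecord("c1", a0 + 1, seq[a0], seq[a0] + rng.choice(list("ACGT")))
                    else:
                        v = VariantRecord("c1", a0 + 1, seq[a0 : a0 + 2], seq[a0])
                    a = assign_indel(t, v, ref)
                    if a is None or a.category not in ("slippage_plus", "slippage_minus"):
                        continue
                    checked += 1
                    new_seq = edited_sequence(seq, v)
                    base = seq[t.start]
                    target = t.n + (1 if a.category == "slippage_plus" else -1)
                    hits = [
                        (s, e)
                        for s, e, b in runs_of(new_seq)
                        if b == base and e - s == target
                        and abs(s - t.start) <= 2
                    ]
                    assert hits, (t, v, a.category)
                    s, e = hits[0]
                    assert new_seq[s - 1] == seq[t.start - 1]
                    assert new_seq[e] == seq[t.end]
        assert checked > 100


class TestStrandSymmetry:
    def test_snv_on_minus_tract_equals_complemented_plus(self):
        seq = "GGTCAAAAATGGC"
        rc = revcomp(seq)
        (t_plus,) = scan_sequence("c1", seq)
        (t_minus,) = scan_sequence("c1", rc)
        L = len(seq)
        for x in range(t_plus.start - 1, t_plus.end + 1):
            ref = seq[x]
            for alt in "ACGT":
                if alt == ref:
                    continue
                a1 = assign_snv(t_plus, VariantRecord("c1", x + 1, ref, alt))
                x2 = L - 1 - x
                a2 = assign_snv(
                    t_minus,
                    VariantRecord("c1", x2 + 1, revcomp(ref), revcomp(alt)),
                )
                assert (a1 is None) == (a2 is None)
                if a1:
                    assert (a1.category, a1.position, a1.substitution) == (
                        a2.category, a2.position, a2.substitution,
                    )


class TestMapVariants:
    def test_single_interior_snv(self):
        seq = "GGTCAAAAATGGC"
        tracts = scan_sequence("c1", seq)
        out = map_variants(tracts, [VariantRecord("c1", 6, "A", "T")], {"c1": seq})
        assert len(out) == 1 and out[0].category == "tract_SNV"

    def test_distant_variant_ignored(self):
        seq = "GGTCAAAAATGGC" + "GC" * 600
        tracts = scan_sequence("c1", seq)
        out = map_variants(tracts, [VariantRecord("c1", 1100, "G", "T")], {"c1": seq})
        assert out == []

    def test_unsorted_input_raises(self):
        seq = "GGTCAAAAATGGC"
        tracts = scan_sequence("c1", seq)
        vs = [VariantRecord("c1", 8, "A", "T"), VariantRecord("c1", 6, "A", "T")]
        with pytest.raises(ValueError, match="sorted"):
            map_variants(tracts, vs, {"c1": seq})

    def test_synthetic_truth_recovered(self, small_sim):
        """Mapped categories/positions equal the generator's truth table."""
        from tractvar.variants import assignments_to_frame

        adf = assignments_to_frame(small_sim["assignments"])
        vt = small_sim["var_truth"].copy()
        vt["position"] = vt["position"].fillna(-1).astype(int)
        cols = ["chrom", "start", "end", "category", "position", "location"]
        truth_keys = sorted(map(tuple, vt[cols].fillna("").values.tolist()))
        assign_keys = sorted(map(tuple, adf[cols].values.tolist()))
        assert truth_keys == assign_keys

    def test_partition_every_event_single_category(self, small_sim):
        from tractvar.variants import assignments_to_frame

        adf = assignments_to_frame(small_sim["assignments"])
        # one assignment per (tract, variant-event) in the synthetic set
        assert len(adf) == len(small_sim["var_truth"])
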