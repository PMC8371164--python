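"""Edit calling, dosage coding and the simulator round-trip."""

import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hbfkit.genotyping import (
    HBG_WINDOW,
    AlleleEdit,
    JunctionQpcrResult,
    call_edits_from_amplicons,
    call_promoter_disruption,
    call_structural,
    code_bcl11a,
    code_zbtb7a,
    count_hbg_dosage,
    genotype_colonies,
    is_frameshift,
)
from hbfkit.simulate import SimConfig, simulate_genotypes

TRUTH_COLUMNS = [
    "colony_id", "hbg_dosage", "bcl11a_series", "bcl11a_e2_dosage",
    "zbtb7a_dosage", "hbb_hbd", "hbd_3p5kb", "hbb_3p5kb",
    "hbb_hbd_inv", "hbd_3p5kb_inv", "hbb_3p5kb_inv",
    "exclude_flag", "exclude_reason",
]


def edit(locus="HBG1_prom", typ="indel", start=100, end=113, bases=13, net=-13):
    return AlleleEdit("C1", locus, typ, start, end, bases, net)


class TestPromoterDisruption:
    @pytest.mark.parametrize(
        "start,end,bases,net,expected",
        [
            (100, 113, 13, -13, True),    # the 13 bp deletion spanning the element
            (105, 107, 2, 0, False),      # 2 bp substitution inside: rule needs >2
            (105, 108, 3, -3, True),      # 3 bp inside: just past the boundary
            (120, 125, 5, -5, False),     # 5 bp deletion fully outside the window
            (98, 101, 3, -3, False),      # only 1 bp overlaps
            (111, 116, 5, -5, False),     # 2 bp overlap at the right edge
        ],
    )
    def test_overlap_rule(self, start, end, bases, net, expected):
        e = edit(start=start, end=end, bases=bases, net=net,
                 typ="substitution" if net == 0 else "indel")
        assert call_promoter_disruption(e) is expected

    def test_insertion_inside_window(self):
        inside = edit(start=106, end=106, bases=4, net=4)
        outside = edit(start=130, end=130, bases=4, net=4)
        assert call_promoter_disruption(inside)
        assert not call_promoter_disruption(outside)

    def test_wt_never_disruptive(self):
        assert not call_promoter_disruption(edit(typ="WT", start=0, end=0, bases=0, net=0))

    def test_wrong_locus_rejected(self):
        with pytest.raises(ValueError, match="promoter"):
            call_promoter_disruption(edit(locus="BCL11A_e2"))

    @given(
        start=st.integers(min_value=0, max_value=112),
        growth=st.integers(min_value=0, max_value=40),
    )
    def test_monotone_in_overlap(self, start, growth):
        """Enlarging a deletion never flips disruptive -> non-disruptive."""
        end = max(start + 1, HBG_WINDOW[0] + 1)
        small = edit(start=start, end=end, bases=end - start, net=-(end - start))
        big = edit(start=start, end=end + growth,
                   bases=end + growth - start, net=-(end + growth - start))
        if call_promoter_disruption(small):
            assert call_promoter_disruption(big)


class TestDosageCoding:
    @pytest.mark.parametrize(
        "calls,expected",
        [([False] * 4, 0), ([True, False, False, False], 1),
         ([True, True, False, False], 2), ([True] * 4, 4)],
    )
    def test_hbg_dosage(self, calls, expected):
        assert count_hbg_dosage(calls) == expected

    def test_hbg_dosage_permutation_invariant(self):
        calls = [True, False, True, False]
        assert count_hbg_dosage(calls) == count_hbg_dosage(calls[::-1]) == 2

    def test_hbg_dosage_needs_four_alleles(self):
        with pytest.raises(ValueError, match="4"):
            count_hbg_dosage([True, False])

    @pytest.mark.parametrize(
        "e2,e4,expected",
        [
            ([False, False], [False, False], 0),
            ([True, False], [False, False], 1),
            ([False, False], [True, False], 2),   # dominant-negative e4 het
            ([True, True], [False, False], 3),
            ([False, False], [True, True], 3),
        ],
    )
    def test_bcl11a_series(self, e2, e4, expected):
        code, reason = code_bcl11a(e2, e4, scheme="allelic_series")
        assert code == expected and reason is None

    def test_bcl11a_e2_e4_het_ambiguous(self):
        code, reason = code_bcl11a([True, False], [True, False])
        assert code is None
        assert reason == "bcl11a_e2_e4_ambiguous"

    def test_bcl11a_e2_dosage_scheme(self):
        assert code_bcl11a([True, True], [], scheme="e2_dosage") == (2, None)
        assert code_bcl11a([True, False], [True, False], scheme="e2_dosage") == (1, None)

    @pytest.mark.parametrize(
        "calls,expected", [([False, False], 0), ([True, False], 1), ([True, True], 2)]
    )
    def test_zbtb7a(self, calls, expected):
        assert code_zbtb7a(calls) == expected

    def test_frameshift_rule(self):
        assert is_frameshift(edit(locus="ZBTB7A", start=60, end=61, bases=1, net=-1))
        assert not is_frameshift(edit(locus="ZBTB7A", start=60, end=63, bases=3, net=-3))


class TestStructuralCalls:
    @pytest.mark.parametrize(
        "internal,del_j,inv_j,dosage,inv,excluded",
        [
            (True, False, False, 0, False, False),
            (True, True, False, 1, False, False),
            (False, True, False, 2, False, False),
            (True, False, True, 0, True, False),    # inversion heterozygote
            (True, True, True, 1, True, False),     # deletion het + inversion
            (False, False, False, None, False, True),  # uninterpretable
        ],
    )
    def test_zygosity_logic(self, internal, del_j, inv_j, dosage, inv, excluded):
        res = JunctionQpcrResult("C1", "hbb_hbd", internal, del_j, inv_j)
        got_dosage, got_inv, reason = call_structural(res)
        assert got_dosage == dosage
        assert got_inv is inv
        assert (reason is not None) is excluded


class TestAmpliconCalling:
    REF = "ACGTACGTAGGCTAGCTAGGATCCGATCGATTACGGATCGATCGT"

    def test_wildtype(self):
        assert call_edits_from_amplicons(self.REF, self.REF) == (0, 0, 0, 0)

    def test_simple_deletion(self):
        start, end, bases, net = call_edits_from_amplicons(
            self.REF, self.REF[:20] + self.REF[25:]
        )
        assert net == -5
        assert bases == 5
        assert end - start == 5

    def test_insertion(self):
        start, end, bases, net = call_edits_from_amplicons(
            self.REF, self.REF[:20] + "TTTT" + self.REF[20:]
        )
        assert net == 4
        assert bases == 4
        assert start == end  # zero-width reference interval


class TestRoundTrip:
    def test_exact_recovery(self, small_dataset):
        """Genotyping applied to simulated allele records reproduces the
        simulator's truth table exactly, colony by colony."""
        _, truth, alleles, junctions = small_dataset
        called = genotype_colonies(
            alleles, junctions,
            metadata=truth[["colony_id", "donor_id", "guide_set_id"]],
        )
        t = truth[TRUTH_COLUMNS].sort_values("colony_id").reset_index(drop=True)
        c = called[TRUTH_COLUMNS].sort_values("colony_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(t, c, check_dtype=False)

    def test_allele_order_invariance(self, small_dataset):
        _, truth, alleles, junctions = small_dataset
        shuffled = alleles.sample(frac=1.0, random_state=5)
        a = genotype_colonies(alleles, junctions).sort_values("colony_id")
        b = genotype_colonies(shuffled, junctions).sort_values("colony_id")
        pd.testing.assert_frame_equal(
            a.reset_index(drop=True), b.reset_index(drop=True)
        )

    def test_hbg_region_sv_excluded(self):
        cfg = SimConfig(seed=3, colonies_per_condition=40, hbg_region_sv_prob=0.3)
        truth, alleles, junctions = simulate_genotypes(cfg)
        excluded = truth.loc[truth["exclude_reason"] == "hbg_region_sv", "colony_id"]
        assert len(excluded) > 0
        called = genotype_colonies(alleles, junctions)
        flagged = called.set_index("colony_id").loc[excluded]
        assert (flagged["exclude_reason"] == "hbg_region_sv").all()
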