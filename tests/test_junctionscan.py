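from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scarscope.junctionscan import (
    JunctionTemplate,
    WellGrid,
    build_predicted_junction,
    classify_junction,
    deletion_sizes,
    find_guide_cut,
    position_profiles,
    revcomp,
    translocation_frequency,
)

from .conftest import random_dna
from .oracles import junction_oracle, profile_recount_oracle

# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------


class TestTemplate:
    def test_explicit_cuts_concatenation(self):
        t = build_predicted_junction("AAAA", "CCCC", cut_a=4, cut_b=0)
        assert t.product_seq == "AAAACCCC"
        assert t.junction_pos == 4

    def test_invariant_product(self, mh_template):
        t = mh_template
        assert t.product_seq == t.parent_a_seq[: t.cut_a] + t.parent_b_seq[t.cut_b:]
        assert t.junction_pos == t.cut_a

    def test_cut_out_of_range(self):
        with pytest.raises(ValueError):
            JunctionTemplate("AAAA", "CCCC", 5, 0)

    def test_forward_guide_cut_17_18_rule(self):
        # hand-computed: protospacer starts at 5, cut between bases 17|18 => 5+17
        guide = "ACTCCAGTCTTTCTAGAAGA"
        parent = "GGGGG" + guide + "TGG" + "AAAAA"
        assert find_guide_cut(parent, guide) == 5 + 17

    def test_reverse_guide_cut(self):
        guide = "ACTCCAGTCTTTCTAGAAGA"
        parent = "TTTTT" + "CCA" + revcomp(guide) + "GGGGG"
        # revcomp(protospacer) starts at 8; cut 3 bp in from the PAM side
        assert find_guide_cut(parent, guide) == 8 + 3

    def test_reverse_strand_product_matches_forward_on_revcomp(self):
        rng = np.random.default_rng(7)
        guide = random_dna(rng, 20)
        parent_fwd = random_dna(rng, 10) + guide + "AGG" + random_dna(rng, 10)
        cut_fwd = find_guide_cut(parent_fwd, guide)
        cut_rev = find_guide_cut(revcomp(parent_fwd), guide)
        assert cut_rev == len(parent_fwd) - cut_fwd

    def test_sixty_bp_parents_against_string_slicing_oracle(self):
        rng = np.random.default_rng(11)
        guide_a = random_dna(rng, 20)
        guide_b = random_dna(rng, 20)
        left_a, left_b = random_dna(rng, 15), random_dna(rng, 12)
        parent_a = left_a + guide_a + "CGG" + random_dna(rng, 22)
        parent_b = left_b + guide_b + "TGG" + random_dna(rng, 25)
        t = build_predicted_junction(parent_a, parent_b, guide_a=guide_a, guide_b=guide_b)
        # independent oracle: locate the guides by string search and slice
        cut_a = parent_a.index(guide_a) + 17
        cut_b = parent_b.index(guide_b) + 17
        assert t.product_seq == parent_a[:cut_a] + parent_b[cut_b:]
        assert t.junction_pos == cut_a

    def test_guide_absent_errors_with_name(self):
        with pytest.raises(ValueError, match="ACTCCAGTCTTTCTAGAAGA"):
            find_guide_cut("ACGT" * 20, "ACTCCAGTCTTTCTAGAAGA")

    def test_guide_multiple_matches_errors(self):
        guide = "ACTCCAGTCTTTCTAGAAGA"
        parent = guide + "AGG" + guide + "AGG"
        with pytest.raises(ValueError, match="2 times"):
            find_guide_cut(parent, guide)

    def test_no_pam_errors(self):
        guide = "ACTCCAGTCTTTCTAGAAGA"
        with pytest.raises(ValueError, match="PAM"):
            find_guide_cut("TTTT" + guide + "ATT", guide)


# ---------------------------------------------------------------------------
# classification: frozen examples
# ---------------------------------------------------------------------------


class TestClassifyExamples:
    def test_worked_mh_deletion(self, mh_template):
        # oracle-verified: junction_oracle gives d=4, ins=0, m=4, span [4, 8)
        call = classify_junction("TTTGGATCCAAA", mh_template, min_anchor=0)
        assert not call.excluded
        assert call.d == 4
        assert call.insertion_seq == ""
        assert call.mh_len == 4
        assert call.mh_seq == "GATC"
        assert (call.mh_start, call.mh_end) == (4, 8)
        assert junction_oracle("TTTGGATCCAAA", mh_template.product_seq)[:3] == (4, 0, 4)

    def test_identity_read(self, mh_template):
        call = classify_junction(mh_template.product_seq, mh_template, min_anchor=0)
        assert (call.d, call.insertion_seq, call.mh_len) == (0, "", 0)

    def test_insertion_read_matches_oracle(self, mh_template):
        # spec lists p=5,s=5,d=6,ins="TT" here, but the second inserted T
        # coincides with product[10]; the maximal-anchor decomposition (and
        # the enumeration oracle) give s=6, d=5, ins="T" -- frozen as such
        read = "TTTGG" + "TT" + "CCAAA"
        call = classify_junction(read, mh_template, min_anchor=0)
        oracle = junction_oracle(read, mh_template.product_seq)
        assert (call.d, len(call.insertion_seq), call.mh_len) == oracle[:3]
        assert (call.p, call.s, call.d, call.insertion_seq) == (5, 6, 5, "T")

    def test_unambiguous_insertion(self, mh_template):
        # product: TTTGGATCGATCCAAA; insert AT at the junction with no
        # deletion (boundary bases chosen not to extend either anchor)
        read = "TTTGGATC" + "AT" + "GATCCAAA"
        call = classify_junction(read, mh_template, min_anchor=0)
        assert (call.d, call.insertion_seq, call.mh_len) == (0, "AT", 0)

    def test_n_near_junction_excluded(self, mh_template):
        call = classify_junction("TTTGGATNCAAA", mh_template, min_anchor=0)
        assert call.excluded

    def test_short_anchor_excluded_under_default(self, mh_template):
        call = classify_junction("TTTGGATCCAAA", mh_template)  # anchors 8 and 4
        assert call.excluded


# ---------------------------------------------------------------------------
# classification: properties against the enumeration oracle
# ---------------------------------------------------------------------------


def _random_case(rng: np.random.Generator) -> tuple[str, str]:
    """Product <= 80 bp, read derived by a junction-proximal edit or fully random."""
    L = int(rng.integers(20, 81))
    j = int(rng.integers(5, L - 4))
    product = random_dna(rng, L)
    mode = rng.integers(0, 4)
    if mode == 0:  # random read
        read = random_dna(rng, int(rng.integers(10, 61)))
    else:  # deletion and/or insertion at the junction
        d = int(rng.integers(0, min(j, L - j, 15) + 1))
        start = int(rng.integers(max(0, j - d), min(L - d, j) + 1))
        ins = random_dna(rng, int(rng.integers(0, 6))) if mode == 2 else ""
        read = product[:start] + ins + product[start + d:]
        read = read[: 60]
    return product, read


def test_oracle_equivalence_500_random_cases():
    rng = np.random.default_rng(314159)
    for _ in range(500):
        product, read = _random_case(rng)
        template = JunctionTemplate(product, "", len(product), 0)
        call = classify_junction(read, template, min_anchor=0)
        d, ins_len, m, span = junction_oracle(read, product)
        assert call.d == d
        assert len(call.insertion_seq) == ins_len
        assert call.mh_len == m
        if d > 0:
            assert (call.mh_start, call.mh_end) == span


@settings(max_examples=200, deadline=None)
@given(st.data())
def test_oracle_equivalence_hypothesis(data):
    product = data.draw(st.text(alphabet="ACGT", min_size=2, max_size=40), label="product")
    read = data.draw(st.text(alphabet="ACGT", min_size=0, max_size=30), label="read")
    template = JunctionTemplate(product, "", len(product), 0)
    call = classify_junction(read, template, min_anchor=0)
    d, ins_len, m, _ = junction_oracle(read, product)
    assert (call.d, len(call.insertion_seq), call.mh_len) == (d, ins_len, m)


@settings(max_examples=150, deadline=None)
@given(st.data())
def test_conservation_and_revcomp_symmetry(data):
    rng_seed = data.draw(st.integers(0, 2**31 - 1))
    rng = np.random.default_rng(rng_seed)
    product, read = _random_case(rng)
    template = JunctionTemplate(product, "", len(product), 0)
    call = classify_junction(read, template, min_anchor=0)
    # conservation
    assert call.p + call.s + len(call.insertion_seq) == len(read)
    assert call.p + call.s + call.d == len(product)
    # reverse-complement symmetry
    rc_template = JunctionTemplate(revcomp(product), "", len(product), 0)
    rc_call = classify_junction(revcomp(read), rc_template, min_anchor=0)
    assert rc_call.d == call.d
    assert len(rc_call.insertion_seq) == len(call.insertion_seq)
    assert rc_call.mh_len == call.mh_len


# ---------------------------------------------------------------------------
# deletion sizes
# ---------------------------------------------------------------------------


class TestDeletionSizes:
    def _call(self, d: int, excluded: bool = False):
        from scarscope.junctionscan.classify import JunctionCall

        return JunctionCall("r", 10, 10, d, 10, 10 + d, "", 0, "", 10, 10, excluded, 20)

    def test_single(self):
        assert deletion_sizes([self._call(4)])[1] == 4

    def test_midpoint_rule_half_integer(self):
        assert deletion_sizes([self._call(0), self._call(37)])[1] == 18.5

    def test_excluded_dropped(self):
        sizes, med = deletion_sizes([self._call(4), self._call(100, excluded=True)])
        assert sizes == [4] and med == 4

    def test_all_excluded_errors(self):
        with pytest.raises(ValueError):
            deletion_sizes([self._call(4, excluded=True)])


# ---------------------------------------------------------------------------
# position profiles
# ---------------------------------------------------------------------------


class TestPositionProfiles:
    def test_no_deletion_all_zero(self, mh_template):
        call = classify_junction(mh_template.product_seq, mh_template, min_anchor=0)
        prof = position_profiles([call], mh_template, window=5)
        assert prof.del_freq.sum() == 0
        assert prof.mh_freq.sum() == 0

    def test_single_read_indicator(self, long_template):
        j = long_template.junction_pos
        product = long_template.product_seq
        read = product[: j - 2] + product[j + 2:]  # deletes [j-2, j+2)
        call = classify_junction(read, long_template, min_anchor=0)
        assert call.d == 4
        prof = position_profiles([call], long_template, window=10)
        covered = prof.coords[prof.del_freq == 1.0]
        # deletion interval equals [j-2, j+2) up to MH-equivalent shift
        assert covered.size == 4
        assert np.all(np.diff(covered) == 1)

    def test_profile_equals_recount_oracle(self, long_template):
        rng = np.random.default_rng(99)
        product = long_template.product_seq
        j = long_template.junction_pos
        calls = []
        for _ in range(50):
            d = int(rng.integers(0, 12))
            start = int(rng.integers(max(0, j - d), min(len(product) - d, j) + 1))
            read = product[:start] + product[start + d:]
            calls.append(classify_junction(read, long_template, min_anchor=0))
        prof = position_profiles(calls, long_template, window=15)
        expected = profile_recount_oracle(
            [(c.del_start, c.del_end) for c in calls], j, 15, len(calls)
        )
        np.testing.assert_allclose(prof.del_freq, expected)
        mh_expected = profile_recount_oracle(
            [(c.mh_start, c.mh_end) for c in calls if c.mh_len > 0], j, 15, len(calls)
        )
        np.testing.assert_allclose(prof.mh_freq, mh_expected)

    def test_requires_nonexcluded(self, mh_template):
        call = classify_junction("NNNNNNNNNNNN", mh_template, min_anchor=0)
        with pytest.raises(ValueError):
            position_profiles([call], mh_template)


# ---------------------------------------------------------------------------
# well grids
# ---------------------------------------------------------------------------


class TestWellGrid:
    def test_none_positive(self):
        grid = WellGrid("c", np.zeros((5, 2), dtype=bool))
        assert translocation_frequency(grid) == 0.0

    def test_two_of_five(self):
        det = np.zeros((5, 2), dtype=bool)
        det[0] = det[3] = True
        assert translocation_frequency(WellGrid("c", det)) == 40.0

    def test_discordant_replicates_hand_enumeration(self):
        # {(+,-), (-,-), (+,+), (-,-), (-,+)} -> 60% under the >=1 rule
        det = np.array(
            [[1, 0], [0, 0], [1, 1], [0, 0], [0, 1]], dtype=bool
        )
        grid = WellGrid("c", det)
        assert translocation_frequency(grid, rule="any") == 60.0
        assert translocation_frequency(grid, rule="all") == 20.0
        assert translocation_frequency(grid, rule="sum") == pytest.approx(40.0)

    def test_rules_validated(self):
        grid = WellGrid("c", np.ones((1, 1), dtype=bool))
        with pytest.raises(ValueError):
            translocation_frequency(grid, rule="median")

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            WellGrid("c", np.zeros((0, 2), dtype=bool))
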