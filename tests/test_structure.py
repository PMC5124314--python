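"""Dot-bracket parsing, loop/bulge annotation, apex finding, and
complementary-strand resolution."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lbsizecleav.structure import (
    UNPAIRED,
    StructureError,
    annotate_loops,
    complementary_segment,
    find_apex,
    max_loop_length,
    parse_dotbracket,
)


def brute_force_run_length(partner, i):
    """Independent oracle: count consecutive unpaired neighbours of i."""
    if partner[i] != UNPAIRED:
        return 0
    n = 1
    j = i - 1
    while j >= 0 and partner[j] == UNPAIRED:
        n += 1
        j -= 1
    j = i + 1
    while j < len(partner) and partner[j] == UNPAIRED:
        n += 1
        j += 1
    return n


@st.composite
def dotbracket(draw):
    """Random valid nested structures via stack simulation."""
    moves = draw(st.lists(st.integers(0, 2), min_size=1, max_size=60))
    out, depth = [], 0
    for m in moves:
        if m == 0:
            out.append("(")
            depth += 1
        elif m == 1 and depth > 0:
            out.append(")")
            depth -= 1
        else:
            out.append(".")
    out.extend(")" * depth)
    return "".join(out)


class TestParseDotbracket:
    @pytest.mark.parametrize(
        "structure,pairs,unpaired",
        [
            ("((..))", {(0, 5), (1, 4)}, {2, 3}),
            ("......", set(), set(range(6))),
            (
                "((..((....))..))",
                {(0, 15), (1, 14), (4, 11), (5, 10)},
                {2, 3, 6, 7, 8, 9, 12, 13},
            ),
        ],
    )
    def test_examples(self, structure, pairs, unpaired):
        pm = parse_dotbracket(structure)
        assert set(pm.pairs()) == pairs
        assert set(np.flatnonzero(pm.partner == UNPAIRED)) == unpaired

    @pytest.mark.parametrize(
        "structure,fragment",
        [
            ("((.)", "position 0"),
            (".))", "position 1"),
            ("(x)", "position 1"),
            ("([.])", "position 1"),
        ],
    )
    def test_malformed_input_names_position(self, structure, fragment):
        with pytest.raises(StructureError, match=fragment):
            parse_dotbracket(structure)

    @given(dotbracket())
    @settings(derandomize=True, max_examples=200)
    def test_parse_render_roundtrip(self, structure):
        pm = parse_dotbracket(structure)
        assert pm.render() == structure
        # symmetry and nestedness of the pair map
        for i, j in pm.pairs():
            assert pm.partner[j] == i and i != j
        open_pairs = []
        for i, j in sorted(pm.pairs()):
            while open_pairs and open_pairs[-1] < i:
                open_pairs.pop()
            if open_pairs:
                assert j < open_pairs[-1], "pseudoknot produced by parser"
            open_pairs.append(j)


class TestAnnotateLoops:
    def test_runs_on_branched_hairpin(self):
        ann = annotate_loops(parse_dotbracket("((..((....))..))"))
        expected = [0, 0, 2, 2, 0, 0, 4, 4, 4, 4, 0, 0, 2, 2, 0, 0]
        assert ann.run_length.tolist() == expected

    def test_fully_paired_stem(self):
        ann = annotate_loops(parse_dotbracket("(())"))
        assert ann.run_length.tolist() == [0, 0, 0, 0]

    def test_worked_example_one_nt_loops(self):
        # window letters UGGgug: unpaired at (1-based) positions 1 and 5,
        # each its own run of size 1 -> l sequence 1,0,0,0,1,0
        ann = annotate_loops(parse_dotbracket(".(((.((...)).)))"))
        assert ann.run_length.tolist()[:6] == [1, 0, 0, 0, 1, 0]

    @given(dotbracket())
    @settings(derandomize=True, max_examples=200)
    def test_matches_brute_force_count(self, structure):
        pm = parse_dotbracket(structure)
        ann = annotate_loops(pm)
        for i in range(len(pm)):
            assert ann.run_length[i] == brute_force_run_length(pm.partner, i)

    def test_runs_are_contiguous_and_uniform(self):
        pm = parse_dotbracket("((..((....))..))")
        ann = annotate_loops(pm)
        for rid in set(ann.run_id.tolist()) - {-1}:
            members = np.flatnonzero(ann.run_id == rid)
            assert np.all(np.diff(members) == 1)
            assert np.unique(ann.run_length[members]).tolist() == [len(members)]


class TestFindApex:
    def test_single_hairpin(self):
        arms = find_apex(parse_dotbracket("((..((....))..))"))
        assert arms.apex == (6, 10)
        assert list(arms.side[:6]) == ["5p"] * 6
        assert list(arms.side[10:]) == ["3p"] * 6

    def test_minimal_hairpin(self):
        assert find_apex(parse_dotbracket("(.)")).apex == (1, 2)

    def test_no_pairs_is_an_error(self):
        with pytest.raises(StructureError, match="no hairpin"):
            find_apex(parse_dotbracket("....."))

    def test_cloverleaf_resolves_to_midmost_innermost_pair(self):
        # two hairpins; the one nearer the sequence midpoint wins
        arms = find_apex(parse_dotbracket("(..)......(..)"))
        assert arms.apex in ((1, 3), (11, 13))
        # deterministic: repeated calls agree
        assert find_apex(parse_dotbracket("(..)......(..)")).apex == arms.apex

    @given(dotbracket())
    @settings(derandomize=True, max_examples=200)
    def test_apex_flanked_by_mutual_partners(self, structure):
        pm = parse_dotbracket(structure)
        if not pm.pairs():
            return
        arms = find_apex(pm)
        start, stop = arms.apex
        assert pm.partner[start - 1] == stop
        assert pm.partner[stop] == start - 1


class TestComplementarySegment:
    def test_fully_paired_window_gives_reversed_partners(self):
        pm = parse_dotbracket("((((((....))))))")
        seg = complementary_segment(0, 6, pm)
        assert seg == [15, 14, 13, 12, 11, 10]

    def test_involution_on_fully_paired_window(self):
        pm = parse_dotbracket("((((((....))))))")
        seg = complementary_segment(0, 6, pm)
        back = complementary_segment(min(seg), 6, pm)
        # same positions, re-expressed in the opposite window's orientation
        assert back == list(range(5, -1, -1))

    def test_own_strand_bulge_pads_apex_distal_gap(self):
        # 1-nt bulge at position 3 of the window arm: 5 partners remain
        pm = parse_dotbracket("(((.((....)))))")
        seg = complementary_segment(0, 6, pm)
        assert seg == [None, 14, 13, 12, 11, 10]

    def test_opposite_strand_bulge_trims_apex_distally(self):
        # opposite strand carries a 1-nt bulge inside the partner span
        pm = parse_dotbracket("((((((....)).))))")
        seg = complementary_segment(0, 6, pm)
        assert seg == [15, 14, 13, 12, 11, 10]

    def test_3p_window_adjusts_at_list_end(self):
        pm = parse_dotbracket("(((.((....)))))")
        # 3p window facing the bulged 5p side: the opposite span includes
        # the unpaired position 3 and is trimmed at the apex-distal (list
        # end) side
        seg = complementary_segment(11, 4, pm)
        assert seg == [4, 3, 2, 1]

    def test_window_of_unpaired_positions_is_an_error(self):
        pm = parse_dotbracket("((..((....))..))")
        with pytest.raises(StructureError, match="no anchor pair"):
            complementary_segment(6, 4, pm)


class TestMaxLoopLength:
    def test_single_structure(self):
        ann = annotate_loops(parse_dotbracket("((..((....))..))"))
        assert max_loop_length([ann]) == 4

    def test_all_paired(self):
        assert max_loop_length([annotate_loops(parse_dotbracket("(())"))]) == 0

    def test_maximum_over_collection(self):
        anns = [
            annotate_loops(parse_dotbracket(s))
            for s in ("(..)", "(.......)", "(...)")
        ]
        assert max_loop_length(anns) == 7

    def test_empty_collection_is_an_error(self):
        with pytest.raises(ValueError):
            max_loop_length([])
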