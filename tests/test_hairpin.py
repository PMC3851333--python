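"""Parsing, pairing topology, duplex alignment and arm-to-arm cut mapping."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dicerscan import (
    CleavageSite,
    GAP,
    Hairpin,
    HairpinParseError,
    PairMap,
    UnpairedOverhangError,
    build_duplex_alignment,
    map_cleavage_between_arms,
    parse_vienna,
    validate_single_loop,
)


class TestParseVienna:
    def test_minimal_record_with_energy(self):
        (h,) = parse_vienna(">h1\nGGGAAACCC\n(((...))) (-1.20)")
        assert (h.id, h.sequence, h.dotbracket, h.mfe) == (
            "h1", "GGGAAACCC", "(((...)))", -1.20,
        )

    def test_energy_suffix_optional(self):
        (h,) = parse_vienna(">h1\nGGGAAACCC\n(((...)))")
        assert h.mfe is None

    def test_multi_record_and_headerless(self):
        hs = parse_vienna("GGGAAACCC\n(((...)))\n>x\nGCAAAAGC\n((....))\n")
        assert [h.id for h in hs] == ["record1", "x"]

    def test_dna_and_case_normalized(self):
        (h,) = parse_vienna(">h\nggtAAAcc\n((....))")
        assert h.sequence == "GGUAAACC"

    @pytest.mark.parametrize(
        "text",
        [
            ">h\nGGGAAACCC\n((..)",          # unbalanced
            ">h\nGGGAAACC\n(((...)))",       # length mismatch
            ">h\nGGNAAACCC\n(((...)))",      # bad residue
        ],
    )
    def test_malformed_records_raise_named_error(self, text):
        with pytest.raises(HairpinParseError, match="h"):
            parse_vienna(text)


class TestPairMap:
    def test_stack_matching(self):
        pm = PairMap.from_dotbracket("(((...)))")
        assert [pm.partner(i) for i in range(1, 10)] == [9, 8, 7, None, None, None, 3, 2, 1]

    def test_all_unpaired(self):
        pm = PairMap.from_dotbracket(".........")
        assert pm.paired_positions() == []

    def test_nested_pairs(self):
        pm = PairMap.from_dotbracket("((..))")
        assert pm.partner(1) == 6 and pm.partner(2) == 5

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(["(", "pair", "."]), min_size=1, max_size=30))
    def test_roundtrip_to_dotbracket(self, ops):
        # Build a random balanced nested structure, then round-trip it.
        db, open_stack = [], 0
        for op in ops:
            if op == "(":
                db.append("(")
                open_stack += 1
            elif op == "pair" and open_stack:
                db.append(")")
                open_stack -= 1
            else:
                db.append(".")
        db += [")"] * open_stack
        s = "".join(db)
        assert PairMap.from_dotbracket(s).to_dotbracket() == s


class TestSingleLoopValidation:
    @pytest.mark.parametrize(
        "db,valid,n",
        [
            ("(((...)))", True, 1),
            ("((...))((...))", False, 2),
            ("((..((...))..((...))))", False, 2),
            (".........", False, 0),
        ],
    )
    def test_loop_counting(self, db, valid, n):
        report = validate_single_loop(PairMap.from_dotbracket(db))
        assert (report.is_single_loop, report.n_loops) == (valid, n)


class TestDuplexAlignment:
    def test_perfect_stem_columns(self):
        h = Hairpin("h", "GGGAAACCC", "(((...)))")
        da = build_duplex_alignment(h)
        assert list(zip(da.arm_tokens, da.complement_tokens)) == [("G", "C")] * 3

    def test_bulged_anchor_arm(self, bulged_hairpin):
        da = build_duplex_alignment(bulged_hairpin)
        assert list(zip(da.arm_tokens, da.complement_tokens)) == [
            ("G", "C"), ("G", "C"), ("A", GAP), ("G", "C"), ("G", "C"),
        ]

    def test_3p_anchor_covers_every_3p_stem_nucleotide(self, bulged_hairpin):
        da = build_duplex_alignment(bulged_hairpin, anchor="3p")
        positions = [da.arm_position(i) for i in range(len(da))]
        assert positions == [9, 10, 11, 12]  # each exactly once, 5'->3'

    def test_full_alignment_inserts_opposite_bulge_columns(self):
        # Pairs 1-10, 2-9, 3-7; position 8 is a bulge on the 3p arm.
        h = Hairpin("h", "GGGAAACACC", "(((...).))")
        assert h.pair_map().partner(2) == 9
        anchored = build_duplex_alignment(h, mode="arm-anchored")
        full = build_duplex_alignment(h, mode="full-alignment")
        assert len(anchored) == 3  # one column per 5p stem nucleotide
        assert len(full) == 4
        gap_col = full.columns[2]
        assert gap_col.token5 == GAP and gap_col.token3 == "A" and gap_col.pos3 == 8

    def test_paired_columns_agree_with_pair_map(self, small_signal_dataset):
        # Wobble G:U columns must be accepted: pairing state comes from the
        # structure, not from a complement table.
        for rec in small_signal_dataset.records[:20]:
            h = rec.hairpin
            pm = h.pair_map()
            da = build_duplex_alignment(h)
            for col in da.columns:
                if col.pos5 is not None and col.pos3 is not None:
                    assert pm.partner(col.pos5) == col.pos3
                    assert col.token5 == h.base(col.pos5)
                    assert col.token3 == h.base(col.pos3)

    def test_multiloop_rejected(self):
        h = Hairpin("h", "GGAAACCGGAAACC", "((...))((...))")
        with pytest.raises(ValueError, match="single stem-loop"):
            build_duplex_alignment(h)


class TestCleavageMapping:
    def test_worked_overhang_example(self, perfect_stem):
        pm = perfect_stem.pair_map()
        mapped = map_cleavage_between_arms(pm, CleavageSite("5p", 8))
        assert mapped == CleavageSite("3p", 20)

    def test_roundtrip_identity_all_interior_cuts(self, perfect_stem):
        pm = perfect_stem.pair_map()
        for cut in range(3, 10):
            site = CleavageSite("5p", cut)
            assert map_cleavage_between_arms(pm, map_cleavage_between_arms(pm, site)) == site

    def test_bulge_at_offset_strict_raises(self):
        # Position 6 (= 8 - 2) is a 5p bulge.
        db = "(((((." + "((((" + "..." + "))))" + ".)))))"
        seq = "GGGGGA" + "GGGG" + "AAA" + "CCCC" + "ACCCCC"
        pm = Hairpin("b", seq, db).pair_map()
        with pytest.raises(UnpairedOverhangError):
            map_cleavage_between_arms(pm, CleavageSite("5p", 8), strict=True)
        with pytest.warns(UserWarning, match="nearest paired"):
            lenient = map_cleavage_between_arms(pm, CleavageSite("5p", 8), strict=False)
        assert lenient.arm == "3p"
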