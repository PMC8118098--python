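"""Grapheme parsing, alignment filtering and GPC tallying."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nonwordvar.lexicon import (
    GPCTable,
    GraphemeRule,
    LexiconEntry,
    LexiconError,
    SyllableParseError,
    build_gpc_table,
    filter_alignable,
    load_default_rules,
    parse_syllable,
)


class TestParseSyllable:
    def test_context_rule_beats_unconditioned(self):
        # C before E/I/Y is the soft pronunciation context (as in MERCY);
        # the parse attributes C to the context rule, Y to its final rule
        rules = [
            GraphemeRule("C", "any", None, order=0),
            GraphemeRule("C", "any", frozenset("EIY"), order=1),
            GraphemeRule("Y", "any", None, order=2),
            GraphemeRule("Y", "syllable_final", None, order=3),
        ]
        toks = parse_syllable("CY", rules)
        assert [(t.grapheme, t.position_class, t.context_set) for t in toks] == [
            ("C", "any", frozenset("EIY")),
            ("Y", "syllable_final", None),
        ]

    def test_single_letter_word_initial(self):
        rules = [GraphemeRule("A", "any", None, order=0),
                 GraphemeRule("A", "word_initial", None, order=1)]
        toks = parse_syllable("A", rules, word_initial=True, word_final=True)
        assert toks[0].grapheme == "A"
        assert toks[0].position_class == "word_initial"

    def test_digraph_consumed_as_one_grapheme(self, single_letter_rules):
        # leftmost-longest: CH is one unit, never C + H
        rules = single_letter_rules + [GraphemeRule("CH", "any", None, order=99)]
        toks = parse_syllable("CHIP", rules)
        assert [t.grapheme for t in toks] == ["CH", "I", "P"]

    @given(st.text(alphabet="ABCDEFGHILMNOPRSTU", min_size=1, max_size=8))
    @settings(max_examples=60, deadline=None)
    def test_greedy_matches_exhaustive_leftmost_longest(self, orth):
        """The greedy parse equals the exhaustive enumeration of all parses
        under the leftmost-longest preference order."""
        inventory = ["CH", "SH", "TH", "EA", "OU"] + list("ABCDEFGHILMNOPRSTU")
        rules = [GraphemeRule(g, "any", None, order=i) for i, g in enumerate(inventory)]
        spellings = set(inventory)

        def all_parses(s):
            if not s:
                yield []
                return
            for k in range(len(s), 0, -1):
                if s[:k] in spellings:
                    for rest in all_parses(s[k:]):
                        yield [s[:k]] + rest

        expected = next(iter(all_parses(orth)), None)  # generation order = leftmost-longest
        got = [t.grapheme for t in parse_syllable(orth, rules)]
        assert got == expected

    def test_unparseable_reports_position(self, single_letter_rules):
        rules = [r for r in single_letter_rules if r.grapheme != "Z"]
        with pytest.raises(SyllableParseError) as exc:
            parse_syllable("AZT", rules)
        assert exc.value.position == 1

    def test_concatenation_roundtrip(self, single_letter_rules):
        rules = single_letter_rules + [GraphemeRule("OO", "any", None, order=50)]
        toks = parse_syllable("BOOT", rules)
        assert "".join(t.grapheme for t in toks) == "BOOT"


class TestFilterAlignable:
    def test_matching_counts_kept_and_paired_in_order(self, single_letter_rules):
        entry = LexiconEntry("CAT", ["CAT"], [("k", "a", "t")])
        aligned = filter_alignable(entry, single_letter_rules)
        assert len(aligned) == 1
        assert [(t.grapheme, p) for t, p in
                zip(aligned[0].graphemes, aligned[0].phonemes)] == [
            ("C", "k"), ("A", "a"), ("T", "t")]

    def test_mismatch_discarded(self, single_letter_rules):
        # 4 graphemes vs 3 phonemes: no unambiguous pairing, dropped
        entry = LexiconEntry("CART", ["CART"], [("k", "a", "t")])
        assert filter_alignable(entry, single_letter_rules) == []

    def test_fully_alignable_lexicon_has_zero_discards(self, single_letter_rules):
        lex = [LexiconEntry("CAT", ["CAT"], [("k", "a", "t")]),
               LexiconEntry("DOG", ["DOG"], [("d", "o", "g")])]
        table = build_gpc_table(lex, single_letter_rules)
        assert table.n_syllables_discarded == 0
        assert table.n_syllables_used == 2


class TestBuildGPCTable:
    def test_deterministic_grapheme_entropy_zero(self, single_letter_rules):
        lex = [LexiconEntry("TAT", ["TAT"], [("t", "a", "t")]),
               LexiconEntry("TOT", ["TOT"], [("t", "o", "t")])]
        table = build_gpc_table(lex, single_letter_rules)
        t_rule = next(r for r in table.entropies if r.grapheme == "T")
        assert table.entropies[t_rule] == 0.0

    def test_uniform_two_way_entropy_ln2(self, single_letter_rules):
        lex = [LexiconEntry("TA", ["TA"], [("t", "a1")]),
               LexiconEntry("DA", ["DA"], [("d", "a2")])]
        table = build_gpc_table(lex, single_letter_rules)
        a_rule = next(r for r in table.entropies if r.grapheme == "A")
        assert table.entropies[a_rule] == pytest.approx(math.log(2), abs=1e-12)

    def test_nine_to_one_entropy(self, single_letter_rules):
        # p = (0.9, 0.1): H = -(0.9 ln 0.9 + 0.1 ln 0.1) = 0.3251
        lex = [LexiconEntry(f"W{i}", ["TA"], [("t", "a1" if i < 9 else "a2")])
               for i in range(10)]
        table = build_gpc_table(lex, single_letter_rules)
        a_rule = next(r for r in table.entropies if r.grapheme == "A")
        expected = -(0.9 * math.log(0.9) + 0.1 * math.log(0.1))
        assert table.entropies[a_rule] == pytest.approx(expected, abs=1e-12)

    def test_relative_frequencies_sum_to_one_per_rule(self, single_letter_rules):
        lex = [LexiconEntry("BAD", ["BAD"], [("b", "a1", "d")]),
               LexiconEntry("BAT", ["BAT"], [("b", "a2", "t")]),
               LexiconEntry("BIT", ["BIT"], [("b", "i", "t")])]
        table = build_gpc_table(lex, single_letter_rules)
        by_rule = {}
        for rec in table.records:
            by_rule.setdefault(rec.rule, 0.0)
            by_rule[rec.rule] += rec.relative_frequency
        assert all(abs(s - 1.0) < 1e-9 for s in by_rule.values())

    def test_entry_order_invariance(self, single_letter_rules):
        lex = [LexiconEntry("BAD", ["BAD"], [("b", "a1", "d")]),
               LexiconEntry("BAT", ["BAT"], [("b", "a2", "t")]),
               LexiconEntry("MIT", ["MIT"], [("m", "i", "t")])]
        t1 = build_gpc_table(lex, single_letter_rules)
        t2 = build_gpc_table(lex[::-1], single_letter_rules)
        assert t1.to_frame().sort_values(["grapheme", "phoneme"]).reset_index(drop=True).equals(
            t2.to_frame().sort_values(["grapheme", "phoneme"]).reset_index(drop=True))

    def test_types_weighting_ignores_duplicate_entries(self, single_letter_rules):
        lex = [LexiconEntry("BAD", ["BAD"], [("b", "a1", "d")]),
               LexiconEntry("BAT", ["BAT"], [("b", "a2", "t")])]
        dup = lex + [LexiconEntry("BAD", ["BAD"], [("b", "a1", "d")])]
        t1 = build_gpc_table(lex, single_letter_rules, weighting="types")
        t2 = build_gpc_table(dup, single_letter_rules, weighting="types")
        assert t1.to_frame().equals(t2.to_frame())
        # under token weighting the duplicate does shift the distribution
        t3 = build_gpc_table(dup, single_letter_rules, weighting="tokens")
        assert not t1.to_frame().equals(t3.to_frame())

    def test_empty_lexicon_rejected(self, single_letter_rules):
        with pytest.raises(LexiconError):
            build_gpc_table([], single_letter_rules)

    @given(data=st.data())
    @settings(max_examples=30, deadline=None)
    def test_counts_equal_naive_nested_loop_oracle(self, data):
        """On tiny lexicons, tallies equal an independent nested-loop count
        and entropies equal the direct -sum(p ln p) evaluation."""
        single_letter_rules = [GraphemeRule(ch, "any", None, order=i)
                               for i, ch in enumerate("ABCD")]
        n_words = data.draw(st.integers(1, 10))
        lex = []
        for w in range(n_words):
            length = data.draw(st.integers(1, 4))
            orth = "".join(data.draw(st.sampled_from("ABCD")) for _ in range(length))
            phon = tuple(data.draw(st.sampled_from(["p1", "p2"])) for _ in range(length))
            lex.append(LexiconEntry(f"W{w}", [orth], [phon]))
        table = build_gpc_table(lex, single_letter_rules, weighting="tokens")

        naive = {}
        for e in lex:
            for orth, phons in zip(e.syllables_orth, e.syllables_phon):
                for letter, ph in zip(orth, phons):  # all 1-letter graphemes
                    naive[(letter, ph)] = naive.get((letter, ph), 0) + 1
        got = {(rec.rule.grapheme, rec.phoneme): rec.count for rec in table.records}
        assert got == naive

        for rule, h in table.entropies.items():
            ps = np.array([rec.relative_frequency for rec in table.records
                           if rec.rule == rule])
            assert h == pytest.approx(float(-(ps * np.log(ps)).sum()), abs=1e-9)
            assert 0.0 <= h <= math.log(len(ps)) + 1e-12


class TestRoundTrip:
    def test_csv_roundtrip_preserves_entropies(self, single_letter_rules, tmp_path):
        lex = [LexiconEntry("BAD", ["BAD"], [("b", "a1", "d")]),
               LexiconEntry("BAT", ["BAT"], [("b", "a2", "t")])]
        table = build_gpc_table(lex, single_letter_rules)
        path = tmp_path / "gpc.csv"
        table.to_csv(path)
        back = GPCTable.from_csv(path)
        orig = {(r.grapheme, r.position_class): h for r, h in table.entropies.items()}
        loaded = {(r.grapheme, r.position_class): h for r, h in back.entropies.items()}
        assert loaded == pytest.approx(orig)

    def test_default_inventory_loads_and_covers_alphabet(self):
        rules = load_default_rules()
        singles = {r.grapheme for r in rules if len(r.grapheme) == 1
                   and r.position_class == "any" and r.context_set is None}
        assert singles == set("ABCDEFGHIJKLMNOPQRSTUVWXYZ")
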