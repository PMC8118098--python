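"""Response-table statistics: diversity, novelty, distances, frequencies."""

import itertools
import math
import unicodedata

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.spatial.distance import hamming

from nonwordvar.responses import (
    ResponseTableError,
    code_novelty,
    count_distinct,
    distinct_counts,
    diversity_table,
    gower_distances,
    normalize_transcription,
    novelty_table,
    pronunciation_frequencies,
    response_diversity,
    validate_responses,
)


def _records(prons, participant="P1", item="I1"):
    return pd.DataFrame({
        "participant": participant, "session": range(1, len(prons) + 1),
        "item": item, "pronunciation": prons,
    })


class TestNormalize:
    @pytest.mark.parametrize("raw,expected", [
        ("ˈbɛbəl", "bɛbəl"),          # primary stress stripped
        ("bɛˌbəl", "bɛbəl"),          # secondary stress stripped
        (" bɛbəl ", "bɛbəl"),         # whitespace trimmed
    ])
    def test_stress_and_whitespace(self, raw, expected):
        assert normalize_transcription(raw) == expected

    def test_unicode_canonical_equivalence(self):
        composed = "déb"                 # e with acute, precomposed
        decomposed = "déb"              # e + combining acute
        assert unicodedata.normalize("NFC", composed) != decomposed
        assert normalize_transcription(composed) == normalize_transcription(decomposed)

    def test_empty_after_stripping_rejected(self):
        with pytest.raises(ResponseTableError):
            normalize_transcription(" ˈ ")


class TestDistinctAndDiversity:
    @pytest.mark.parametrize("prons,expected", [
        (list("AAAAA"), 1),
        (list("ABCDE"), 5),
        (list("ABAB"), 2),
    ])
    def test_count_distinct(self, prons, expected):
        assert count_distinct(prons) == expected

    def test_identical_responses_zero_diversity(self):
        assert response_diversity(list("AAAAA")) == 0.0

    def test_five_distinct_is_ln5(self):
        d = response_diversity(list("ABCDE"))
        assert d == pytest.approx(math.log(5), abs=1e-12)
        assert round(d, 1) == 1.6  # the printed maximum for five sessions

    def test_three_two_split_closed_form(self):
        d = response_diversity(list("AAABB"))
        assert d == pytest.approx(-(0.6 * math.log(0.6) + 0.4 * math.log(0.4)), abs=1e-12)

    @given(st.lists(st.sampled_from("ABC"), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_diversity_bounds_property(self, prons):
        d = response_diversity(prons)
        k = count_distinct(prons)
        assert -1e-12 <= d <= math.log(k) + 1e-12
        assert math.log(k) <= math.log(len(prons)) + 1e-12
        assert (d == 0.0) == (k == 1)

    @given(st.lists(st.sampled_from("ABCD"), min_size=2, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_merging_categories_never_increases_diversity(self, prons):
        merged = ["A" if p == "B" else p for p in prons]
        assert response_diversity(merged) <= response_diversity(prons) + 1e-12


class TestNovelty:
    @pytest.mark.parametrize("prons,flags", [
        (list("AAAAA"), [0, 0, 0, 0]),
        (list("ABBBB"), [1, 0, 0, 0]),
        (list("AAABA"), [0, 0, 1, 0]),  # late change; return to A is old
        (list("ABCDE"), [1, 1, 1, 1]),
    ])
    def test_worked_examples(self, prons, flags):
        assert code_novelty(_records(prons)) == flags

    def test_session_gap_rejected(self):
        rec = _records(list("AAB"))
        rec.loc[2, "session"] = 5
        with pytest.raises(ResponseTableError):
            code_novelty(rec)

    @given(st.lists(st.sampled_from("ABC"), min_size=1, max_size=6))
    @settings(max_examples=100, deadline=None)
    def test_distinct_equals_one_plus_novelty_sum(self, prons):
        """Ties the distinct-count and novelty analyses together."""
        flags = code_novelty(_records(prons))
        assert count_distinct(prons) == 1 + sum(flags)

    def test_novelty_table_long_format(self):
        df = validate_responses(pd.concat([
            _records(list("AABBA"), "P1"), _records(list("AAAAA"), "P2")]))
        nt = novelty_table(df)
        assert set(nt["session"]) == {2, 3, 4, 5}
        assert nt.groupby("participant")["novel"].sum().to_dict() == {"P1": 1, "P2": 0}


class TestGower:
    def _table(self, matrix, session=1):
        rows = []
        for p, prons in matrix.items():
            for i, pron in enumerate(prons):
                if pron is not None:
                    rows.append({"participant": p, "session": session,
                                 "item": f"I{i}", "pronunciation": pron})
        return pd.DataFrame(rows)

    def test_identical_rows_distance_zero(self):
        gd = gower_distances(self._table({"P1": list("AAB"), "P2": list("AAB")}))
        assert gd["distance"].iloc[0] == 0.0

    def test_fully_different_rows_distance_one(self):
        gd = gower_distances(self._table({"P1": list("AAA"), "P2": list("BBB")}))
        assert gd["distance"].iloc[0] == 1.0

    def test_half_mismatch(self):
        a = ["A"] * 25 + ["B"] * 25
        b = ["A"] * 50
        gd = gower_distances(self._table({"P1": a, "P2": b}))
        assert gd["distance"].iloc[0] == 0.5
        assert gd["n_items_compared"].iloc[0] == 50

    def test_missing_items_compared_on_overlap(self):
        gd = gower_distances(self._table({"P1": ["A", "B", None], "P2": ["A", "C", "D"]}))
        assert gd["n_items_compared"].iloc[0] == 2
        assert gd["distance"].iloc[0] == 0.5

    @given(data=st.data())
    @settings(max_examples=60, deadline=None)
    def test_matches_naive_double_loop_oracle(self, data):
        n_p = data.draw(st.integers(2, 5))
        n_i = data.draw(st.integers(1, 6))
        matrix = {f"P{j}": [data.draw(st.sampled_from("AB"))
                            for _ in range(n_i)] for j in range(n_p)}
        gd = gower_distances(self._table(matrix))
        got = {(r.participant_a, r.participant_b): r.distance for r in gd.itertuples()}
        for a, b in itertools.combinations(sorted(matrix), 2):
            mism = sum(x != y for x, y in zip(matrix[a], matrix[b])) / n_i
            assert got[(a, b)] == pytest.approx(mism)
            # scipy's hamming distance is the same quantity for equal-length rows
            assert got[(a, b)] == pytest.approx(
                hamming(np.array(matrix[a], object) != "A",
                        np.array(matrix[b], object) != "A"))

    def test_pair_counts_with_final_session_dropout(self, default_sim):
        """22 participants in sessions 1-4 and 20 in session 5 give
        4 x 231 + 190 = 1,114 distances."""
        responses, _ = default_sim
        with pytest.warns(UserWarning):
            gd = gower_distances(responses)
        per_session = gd.groupby("session").size()
        assert per_session.loc[1] == 231
        assert per_session.loc[5] == 190
        assert len(gd) == 1114


class TestFrequencies:
    def _df(self):
        rows = [
            ("P1", 1, "I1", "x"), ("P2", 1, "I1", "x"), ("P3", 1, "I1", "y"),
            ("P1", 2, "I1", "y"), ("P2", 2, "I1", "y"), ("P3", 2, "I1", "y"),
            ("P1", 3, "I1", "y"), ("P2", 3, "I1", "y"), ("P3", 3, "I1", "y"),
        ]
        return pd.DataFrame(rows, columns=["participant", "session", "item", "pronunciation"])

    def test_counts_and_zero_fill(self):
        pf = pronunciation_frequencies(self._df())
        x = pf[pf["pronunciation"] == "x"].set_index("session")["frequency"]
        assert x.loc[1] == 2          # used by two participants in session 1
        assert x.loc[2] == 0          # never used later: zero-filled
        assert x.loc[3] == 0
        y = pf[pf["pronunciation"] == "y"].set_index("session")["frequency"]
        assert y.loc[3] == 3          # everyone present

    def test_last_session_exclusion_flag(self):
        pf = pronunciation_frequencies(self._df(), drop_last_session=True)
        assert pf["session"].max() == 2

    def test_frequency_bounded_by_session_headcount(self, default_sim):
        responses, _ = default_sim
        pf = pronunciation_frequencies(responses)
        head = responses.groupby("session")["participant"].nunique()
        merged = pf.merge(head.rename("headcount"), on="session")
        assert (merged["frequency"] <= merged["headcount"]).all()
        # per item and session the counts add up to the responding headcount
        totals = pf.groupby(["item", "session"])["frequency"].sum().reset_index()
        obs = responses.groupby(["item", "session"]).size().reset_index(name="n")
        check = totals.merge(obs, on=["item", "session"])
        assert (check["frequency"] == check["n"]).all()


class TestValidation:
    def test_duplicate_record_rejected(self):
        df = pd.concat([_records(list("AB")), _records(list("AB"))])
        with pytest.raises(ResponseTableError, match="duplicate"):
            validate_responses(df)

    def test_non_contiguous_sessions_rejected(self):
        df = _records(list("AB"))
        df["session"] = [1, 3]
        with pytest.raises(ResponseTableError, match="contiguous"):
            validate_responses(df)

    def test_distinct_counts_table(self):
        df = validate_responses(pd.concat([
            _records(list("AABBA"), "P1"), _records(list("CCCCC"), "P2")]))
        dc = distinct_counts(df).set_index("participant")
        assert dc.loc["P1", "n_distinct"] == 2
        assert dc.loc["P2", "n_distinct"] == 1
        assert (dc["n_sessions"] == 5).all()

    def test_diversity_table_agrees_with_scalar_function(self):
        df = validate_responses(pd.concat([
            _records(list("AABBA"), "P1"), _records(list("ABCDE"), "P2")]))
        dt = diversity_table(df).set_index("participant")
        assert dt.loc["P1", "diversity"] == pytest.approx(response_diversity(list("AABBA")))
        assert dt.loc["P2", "diversity"] == pytest.approx(math.log(5))
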