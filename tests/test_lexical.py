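import itertools
import math
from functools import lru_cache

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clinsts.errors import StateError
from clinsts.lexical import (
    IdfModel,
    bag_similarity,
    dice,
    generalized_jaccard,
    jaccard,
    jaro,
    levenshtein_similarity,
    needleman_wunsch_similarity,
    ochiai,
    qgram_profile,
    qgram_similarity,
    smith_waterman_similarity,
    tfidf_cosine,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def lev_oracle(a: str, b: str) -> int:
    @lru_cache(maxsize=None)
    def rec(i: int, j: int) -> int:
        if i == 0:
            return j
        if j == 0:
            return i
        return min(
            rec(i - 1, j) + 1,
            rec(i, j - 1) + 1,
            rec(i - 1, j - 1) + (a[i - 1] != b[j - 1]),
        )

    return rec(len(a), len(b))


def nw_oracle(a: str, b: str) -> float:
    """Best global alignment score by plain recursion (match +1, mismatch/gap -1)."""
    if not a:
        return -len(b)
    if not b:
        return -len(a)
    sub = nw_oracle(a[1:], b[1:]) + (1 if a[0] == b[0] else -1)
    return max(sub, nw_oracle(a[1:], b) - 1, nw_oracle(a, b[1:]) - 1)


def sw_oracle(a: str, b: str) -> float:
    """Best local alignment = best global alignment over all substring pairs."""
    best = 0.0
    subs_a = {a[i:j] for i in range(len(a)) for j in range(i + 1, len(a) + 1)}
    subs_b = {b[i:j] for i in range(len(b)) for j in range(i + 1, len(b) + 1)}
    for sa in subs_a:
        for sb in subs_b:
            best = max(best, nw_oracle(sa, sb))
    return best


# ---------------------------------------------------------------------------
# token-based measures
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "fn, expected",
    [(jaccard, 2 / 4), (dice, 2 * 2 / 6), (ochiai, 2 / 3)],
)
def test_set_measures_on_overlapping_sets(fn, expected):
    assert fn({"a", "b", "c"}, {"b", "c", "d"}) == pytest.approx(expected)


@pytest.mark.parametrize("fn", [jaccard, dice, ochiai, generalized_jaccard])
def test_set_measures_identity_disjoint_empty(fn):
    assert fn({"x", "y"}, {"x", "y"}) == 1.0
    assert fn({"aaa"}, {"zzz"}) == 0.0
    assert fn(set(), set()) == 1.0


def test_jaro_known_values():
    assert jaro("martha", "marhta") == pytest.approx(17 / 18)  # m=6, t=1
    assert jaro("abc", "abc") == 1.0
    assert jaro("abc", "xyz") == 0.0
    assert jaro("", "abc") == 0.0


def test_generalized_jaccard_matches_similar_tokens():
    # Jaro("jon","john") = (3/3 + 3/4 + 3/3)/3 = 11/12 >= 0.6 -> matched
    assert jaro("jon", "john") == pytest.approx(11 / 12)
    assert generalized_jaccard({"jon"}, {"john"}, threshold=0.6) == 1.0
    assert generalized_jaccard({"jon"}, {"john"}, threshold=0.99) == 0.0


@settings(derandomize=True, max_examples=200, deadline=None)
@given(
    st.sets(st.text(alphabet="abcd", min_size=1, max_size=4), max_size=6),
    st.sets(st.text(alphabet="abcd", min_size=1, max_size=4), max_size=6),
)
def test_generalized_jaccard_at_threshold_one_reduces_to_jaccard(x, y):
    assert generalized_jaccard(x, y, threshold=1.0) == pytest.approx(jaccard(x, y))


def test_tfidf_cosine_hand_computed_corpus():
    # Corpus d1="apple banana", d2="banana cherry", d3="cherry date";
    # smoothed idf = ln((1+N)/(1+df)) + 1 with N=3, raw tf, L2 norm.
    model = IdfModel().fit([["apple", "banana"], ["banana", "cherry"], ["cherry", "date"]])
    i1 = math.log(4 / 2) + 1  # df=1 terms
    i2 = math.log(4 / 3) + 1  # df=2 terms
    # d1 = (i1, i2) over (apple, banana); d2 = (i2, i2) over (banana, cherry);
    # they share only "banana": cos = i2*i2 / (|d1| * |d2|)
    expected = (i2 * i2) / (math.hypot(i1, i2) * math.hypot(i2, i2))
    assert tfidf_cosine(["apple", "banana"], ["banana", "cherry"], model) == pytest.approx(expected)
    assert tfidf_cosine(["apple", "banana"], ["apple", "banana"], model) == pytest.approx(1.0)
    assert tfidf_cosine(["apple"], ["date"], model) == 0.0


def test_tfidf_requires_fitted_model():
    with pytest.raises(StateError):
        tfidf_cosine(["a"], ["a"], IdfModel())


# ---------------------------------------------------------------------------
# character-based measures
# ---------------------------------------------------------------------------

def test_qgram_similarity_worked_example():
    # profiles {abc,bcd} vs {abc,bce}: distance 2, totals 2+2
    assert qgram_similarity("abcd", "abce", q=3) == pytest.approx(0.5)
    assert qgram_similarity("abcdef", "abcdef", q=3) == 1.0
    assert qgram_similarity("ab", "abcd", q=3) == 0.0  # one profile empty
    assert qgram_similarity("ab", "cd", q=3) == 1.0    # both empty


@settings(derandomize=True, max_examples=300, deadline=None)
@given(st.text(alphabet="abc", max_size=12), st.integers(min_value=1, max_value=4))
def test_qgram_profile_matches_brute_force_counting(s, q):
    profile = qgram_profile(s, q)
    assert all(len(g) == q for g in profile)
    assert sum(profile.values()) == max(0, len(s) - q + 1)
    for gram in set(profile):
        brute = sum(1 for i in range(len(s)) if s[i : i + q] == gram)
        assert profile[gram] == brute


# ---------------------------------------------------------------------------
# sequence-based measures
# ---------------------------------------------------------------------------

def test_levenshtein_similarity_examples():
    assert levenshtein_similarity("kitten", "sitting") == pytest.approx(1 - 3 / 7)
    assert levenshtein_similarity("", "") == 1.0
    assert levenshtein_similarity("", "abc") == 0.0


def test_levenshtein_matches_recursive_oracle_exhaustively():
    strings = [
        "".join(t)
        for n in range(0, 4)
        for t in itertools.product("abc", repeat=n)
    ]
    for a in strings:
        for b in strings:
            d = lev_oracle(a, b)
            if max(len(a), len(b)) == 0:
                assert levenshtein_similarity(a, b) == 1.0
            else:
                assert levenshtein_similarity(a, b) == pytest.approx(
                    1 - d / max(len(a), len(b))
                )


def test_levenshtein_matches_oracle_on_random_length6_pairs(rng):
    letters = np.array(list("abc"))
    for _ in range(300):
        a = "".join(rng.choice(letters, size=rng.integers(0, 7)))
        b = "".join(rng.choice(letters, size=rng.integers(0, 7)))
        d = lev_oracle(a, b)
        expected = 1.0 if not a and not b else 1 - d / max(len(a), len(b))
        assert levenshtein_similarity(a, b) == pytest.approx(expected)


def test_bag_similarity_examples():
    assert bag_similarity("ab", "ba") == 1.0  # anagrams: equal multisets
    assert bag_similarity("abc", "abc") == 1.0
    # multiset(hello)-multiset(help) = {l,o}; reverse = {p}; dist 2, max len 5
    assert bag_similarity("hello", "help") == pytest.approx(1 - 2 / 5)


def test_needleman_wunsch_worked_example_and_bounds():
    # "gat" vs "gct": best global score 1 -> (1+3)/6
    assert needleman_wunsch_similarity("gat", "gct") == pytest.approx(2 / 3)
    assert needleman_wunsch_similarity("abc", "abc") == 1.0
    assert needleman_wunsch_similarity("aaa", "zzz") == 0.0
    assert needleman_wunsch_similarity("", "") == 1.0
    assert needleman_wunsch_similarity("", "ab") == 0.0


def test_smith_waterman_worked_example():
    # best local alignment of "aab"/"zaaz" is "aa" vs "aa": score 2, shorter len 3
    assert smith_waterman_similarity("aab", "zaaz") == pytest.approx(2 / 3)
    assert smith_waterman_similarity("abc", "abc") == 1.0
    assert smith_waterman_similarity("abc", "xyz") == 0.0


def test_alignment_scores_match_enumeration_oracle(rng):
    letters = np.array(list("abz"))
    for _ in range(60):
        a = "".join(rng.choice(letters, size=rng.integers(1, 5)))
        b = "".join(rng.choice(letters, size=rng.integers(1, 5)))
        L = max(len(a), len(b))
        assert needleman_wunsch_similarity(a, b) == pytest.approx(
            float(np.clip((nw_oracle(a, b) + L) / (2 * L), 0, 1))
        )
        assert smith_waterman_similarity(a, b) == pytest.approx(
            float(np.clip(sw_oracle(a, b) / min(len(a), len(b)), 0, 1))
        )


# ---------------------------------------------------------------------------
# shared contract
# ---------------------------------------------------------------------------

_STRING_MEASURES = [
    jaro,
    lambda a, b: qgram_similarity(a, b, 3),
    levenshtein_similarity,
    bag_similarity,
    needleman_wunsch_similarity,
    smith_waterman_similarity,
]


@settings(derandomize=True, max_examples=150, deadline=None)
@given(st.text(alphabet="abcz ", max_size=8), st.text(alphabet="abcz ", max_size=8))
def test_string_measures_symmetric_and_bounded(a, b):
    for fn in _STRING_MEASURES:
        sab, sba = fn(a, b), fn(b, a)
        assert sab == pytest.approx(sba)
        assert 0.0 <= sab <= 1.0
        assert fn(a, a) == pytest.approx(1.0)


@settings(derandomize=True, max_examples=150, deadline=None)
@given(
    st.sets(st.text(alphabet="abcz", min_size=1, max_size=5), max_size=6),
    st.sets(st.text(alphabet="abcz", min_size=1, max_size=5), max_size=6),
)
def test_set_measures_symmetric_and_bounded(x, y):
    for fn in (jaccard, dice, ochiai, generalized_jaccard):
        sxy, syx = fn(x, y), fn(y, x)
        assert sxy == pytest.approx(syx)
        assert 0.0 <= sxy <= 1.0
        assert fn(x, x) == 1.0
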