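"""Token-, character- and sequence-based similarity measures.

Eleven measures, each symmetric and normalized to [0, 1]:

* token-based (5): Jaccard, generalized Jaccard (Jaro-matched tokens),
  Dice, Ochiai, tf-idf cosine;
* character-based (2): q-gram profile similarity at q = 3 and q = 4;
* sequence-based (4): bag, Levenshtein, Needleman-Wunsch (global
  alignment) and Smith-Waterman (local alignment) similarities.

Degenerate inputs follow one convention throughout: two empty inputs are
identical (similarity 1); an empty input against a non-empty one is maximally
dissimilar (similarity 0).  The distance-to-similarity normalizations are
documented per function since the measures are conventionally defined as
distances or raw alignment scores.
"""

from __future__ import annotations

from collections import Counter
from collections.abc import Iterable
from dataclasses import dataclass

import edlib
import numpy as np
from Bio import Align
from sklearn.feature_extraction.text import TfidfVectorizer

from .errors import StateError
from .textprep import TokenSequence

__all__ = [
    "jaccard",
    "generalized_jaccard",
    "jaro",
    "dice",
    "ochiai",
    "IdfModel",
    "tfidf_cosine",
    "qgram_profile",
    "qgram_similarity",
    "levenshtein_similarity",
    "bag_similarity",
    "needleman_wunsch_similarity",
    "smith_waterman_similarity",
    "AlignmentScoring",
]

#: q-gram window sizes used in the assembled feature vector.
DEFAULT_QGRAM_SIZES = (3, 4)
#: Jaro threshold above which two tokens count as "the same" in the
#: generalized Jaccard measure.
DEFAULT_JARO_THRESHOLD = 0.6


def _as_set(x: Iterable[str] | frozenset[str]) -> frozenset[str]:
    if isinstance(x, TokenSequence):
        return x.as_set()
    return frozenset(x)


# ---------------------------------------------------------------------------
# Token-based measures
# ---------------------------------------------------------------------------

def jaccard(x: Iterable[str], y: Iterable[str]) -> float:
    """|X ∩ Y| / |X ∪ Y|; two empty sets are identical (1)."""
    xs, ys = _as_set(x), _as_set(y)
    if not xs and not ys:
        return 1.0
    return len(xs & ys) / len(xs | ys)


def dice(x: Iterable[str], y: Iterable[str]) -> float:
    """2|X ∩ Y| / (|X| + |Y|); two empty sets are identical (1)."""
    xs, ys = _as_set(x), _as_set(y)
    if not xs and not ys:
        return 1.0
    return 2 * len(xs & ys) / (len(xs) + len(ys))


def ochiai(x: Iterable[str], y: Iterable[str]) -> float:
    """|X ∩ Y| / sqrt(|X| |Y|); one empty set gives 0, two give 1."""
    xs, ys = _as_set(x), _as_set(y)
    if not xs and not ys:
        return 1.0
    if not xs or not ys:
        return 0.0
    return len(xs & ys) / float(np.sqrt(len(xs) * len(ys)))


def jaro(a: str, b: str) -> float:
    """Jaro similarity of two strings.

    Characters match if equal and within a window of
    ``floor(max(|a|,|b|)/2) - 1`` positions; transpositions count half.
    """
    if a == b:
        return 1.0
    la, lb = len(a), len(b)
    if la == 0 or lb == 0:
        return 0.0
    window = max(la, lb) // 2 - 1
    match_a = [False] * la
    match_b = [False] * lb
    m = 0
    for i, ca in enumerate(a):
        lo = max(0, i - window)
        hi = min(lb, i + window + 1)
        for j in range(lo, hi):
            if not match_b[j] and b[j] == ca:
                match_a[i] = match_b[j] = True
                m += 1
                break
    if m == 0:
        return 0.0
    # transpositions: matched characters out of relative order, halved
    bj = [b[j] for j in range(lb) if match_b[j]]
    t = sum(ca != cb for ca, cb in zip((a[i] for i in range(la) if match_a[i]), bj)) / 2
    return (m / la + m / lb + (m - t) / m) / 3


def generalized_jaccard(
    x: Iterable[str],
    y: Iterable[str],
    threshold: float = DEFAULT_JARO_THRESHOLD,
    sum_similarities: bool = False,
) -> float:
    """Jaccard where tokens count as equal when their Jaro similarity ≥ *threshold*.

    Candidate token pairs are matched greedily in order of decreasing Jaro
    similarity (ties broken lexicographically), each token used at most once.
    With ``sum_similarities`` the numerator adds the matched pairs' Jaro
    values instead of counting them.  At ``threshold=1`` only identical
    tokens can match, so the measure reduces to plain Jaccard.
    """
    xs, ys = sorted(_as_set(x)), sorted(_as_set(y))
    if not xs and not ys:
        return 1.0
    if not xs or not ys:
        return 0.0
    candidates = []
    for xi in xs:
        for yj in ys:
            s = jaro(xi, yj)
            if s >= threshold:
                candidates.append((-s, xi, yj, s))
    candidates.sort()
    used_x: set[str] = set()
    used_y: set[str] = set()
    matched = 0.0
    n_matched = 0
    for _, xi, yj, s in candidates:
        if xi in used_x or yj in used_y:
            continue
        used_x.add(xi)
        used_y.add(yj)
        matched += s
        n_matched += 1
    numer = matched if sum_similarities else float(n_matched)
    return numer / (len(xs) + len(ys) - n_matched)


class IdfModel:
    """tf-idf weighting fitted on a sentence corpus.

    Wraps a :class:`~sklearn.feature_extraction.text.TfidfVectorizer` over
    pre-tokenized sequences with smoothed idf ``ln((1+N)/(1+df)) + 1``, raw
    term counts and L2-normalized vectors.
    """

    def __init__(self) -> None:
        self._vec = TfidfVectorizer(
            analyzer=lambda toks: list(toks), norm="l2", smooth_idf=True
        )
        self._fitted = False

    def fit(self, corpus: Iterable[Iterable[str]]) -> "IdfModel":
        docs = [list(doc) for doc in corpus]
        self._vec.fit(docs)
        self._fitted = True
        return self

    @property
    def fitted(self) -> bool:
        return self._fitted

    def transform(self, tokens: Iterable[str]) -> np.ndarray:
        if not self._fitted:
            raise StateError("IdfModel.transform called before fit()")
        return self._vec.transform([list(tokens)]).toarray()[0]


def tfidf_cosine(x: Iterable[str], y: Iterable[str], idf_model: IdfModel) -> float:
    """Cosine of the tf-idf vectors of two token sequences.

    Sequences whose tokens are all outside the fitted vocabulary have zero
    vectors; two such sequences score 1 only if they are token-identical.
    """
    if not idf_model.fitted:
        raise StateError("tfidf_cosine requires a fitted IdfModel")
    xt, yt = list(x), list(y)
    if not xt and not yt:
        return 1.0
    if not xt or not yt:
        return 0.0
    u = idf_model.transform(xt)
    v = idf_model.transform(yt)
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 1.0 if xt == yt else 0.0
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


# ---------------------------------------------------------------------------
# Character-based measures
# ---------------------------------------------------------------------------

def qgram_profile(s: str, q: int) -> Counter[str]:
    """Multiset of the length-*q* substrings of *s* (unpadded sliding window)."""
    if q < 1:
        raise ValueError("q must be >= 1")
    return Counter(s[i : i + q] for i in range(len(s) - q + 1))


def qgram_similarity(a: str, b: str, q: int) -> float:
    """1 − d/(N_a + N_b) with profile distance d = Σ_g |count_a(g) − count_b(g)|."""
    pa, pb = qgram_profile(a, q), qgram_profile(b, q)
    na, nb = sum(pa.values()), sum(pb.values())
    if na == 0 and nb == 0:
        return 1.0
    if na == 0 or nb == 0:
        return 0.0
    d = sum(abs(pa[g] - pb[g]) for g in pa.keys() | pb.keys())
    return 1.0 - d / (na + nb)


# ---------------------------------------------------------------------------
# Sequence-based measures
# ---------------------------------------------------------------------------

def _levenshtein_distance(a: str, b: str) -> int:
    if a == b:
        return 0
    if not a or not b:
        return max(len(a), len(b))
    return edlib.align(a, b, task="distance")["editDistance"]


def levenshtein_similarity(a: str, b: str) -> float:
    """1 − edit_distance(a, b) / max(|a|, |b|)."""
    if not a and not b:
        return 1.0
    return 1.0 - _levenshtein_distance(a, b) / max(len(a), len(b))


def bag_similarity(a: str, b: str) -> float:
    """1 − bag_distance / max(|a|, |b|).

    The bag distance is ``max(|multiset(a) − multiset(b)|,
    |multiset(b) − multiset(a)|)``, a cheap lower bound on edit distance.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    ca, cb = Counter(a), Counter(b)
    d = max(sum((ca - cb).values()), sum((cb - ca).values()))
    return 1.0 - d / max(len(a), len(b))


@dataclass(frozen=True)
class AlignmentScoring:
    """Match / mismatch / linear-gap scores for the alignment similarities."""

    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -1.0

    def aligner(self, mode: str) -> Align.PairwiseAligner:
        return Align.PairwiseAligner(
            match_score=self.match,
            mismatch_score=self.mismatch,
            open_gap_score=self.gap,
            extend_gap_score=self.gap,
            mode=mode,
        )


DEFAULT_SCORING = AlignmentScoring()


def needleman_wunsch_similarity(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Global-alignment score rescaled to [0, 1].

    With the default unit scoring the raw score lies in
    [−max(|a|,|b|)·1, max(|a|,|b|)·1] for the alignments that matter, so the
    similarity is ``(score + L) / (2L)`` with ``L = max(|a|, |b|)``, clipped
    to [0, 1]: self-alignment maps to 1, an all-mismatch alignment to 0.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    score = scoring.aligner("global").score(a, b)
    L = max(len(a), len(b))
    hi = L * scoring.match
    lo = -L * scoring.match
    return float(np.clip((score - lo) / (hi - lo), 0.0, 1.0))


def smith_waterman_similarity(
    a: str, b: str, scoring: AlignmentScoring = DEFAULT_SCORING
) -> float:
    """Best local-alignment score normalized by the shorter string's self-score.

    No positive-scoring local alignment (character-disjoint strings) gives 0;
    identical strings give 1.
    """
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    score = scoring.aligner("local").score(a, b)
    denom = min(len(a), len(b)) * scoring.match
    return float(np.clip(score / denom, 0.0, 1.0))
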