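"""Sentence normalization and tokenization.

Pre-processing runs in four steps: lowercase the sentence, split words that
are joined by punctuation (``/``, ``.-``, a period between two letters, and
quoting apostrophes), tokenize with a Treebank-style tokenizer, and
optionally drop stopwords and punctuation-only tokens.  All downstream
similarity features consume the output of this module, so every rule here is
deterministic and idempotent.
"""

from __future__ import annotations

import re
import string
import unicodedata
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources

from .errors import InvalidInputError

#: Characters that make a token "punctuation-only" when it contains nothing else.
PUNCTUATION_SET = frozenset(string.punctuation) | frozenset("‘’“”–—`")

_SLASH = re.compile(r"\s*/\s*")
_DOT_DASH = re.compile(r"\s*\.\s*-\s*")
# A period squeezed between two letters ("content.caller") marks a missing
# sentence boundary; a period between digits is a decimal point and survives.
_DOT_BETWEEN_LETTERS = re.compile(r"(?<=[^\W\d_])\.(?=[^\W\d_])", re.UNICODE)
# Straight apostrophe in quoting position (not inside a contraction).
_QUOTE_APOS = re.compile(r"(?<![^\W\d_])'|'(?![^\W\d_])", re.UNICODE)
_CURLY_APOS = re.compile(r"[‘’]")
_WS = re.compile(r"\s+")


def normalize(text: str) -> str:
    """Lowercase *text* and space out punctuation that glues words together.

    Raises :class:`InvalidInputError` on empty (or whitespace-only) input.
    The function is idempotent: applying it twice equals applying it once.
    """
    if text is None or not text.strip():
        raise InvalidInputError("cannot normalize an empty sentence")
    out = unicodedata.normalize("NFC", text).lower()
    out = _CURLY_APOS.sub("'", out)
    out = _DOT_DASH.sub(". - ", out)
    out = _SLASH.sub(" / ", out)
    out = _DOT_BETWEEN_LETTERS.sub(". ", out)
    out = _QUOTE_APOS.sub(" ' ", out)
    return _WS.sub(" ", out).strip()


@dataclass(frozen=True)
class TokenSequence:
    """An ordered token list plus a flag recording whether stopwords were removed."""

    tokens: tuple[str, ...]
    stop_filtered: bool = False

    def __post_init__(self) -> None:
        if any(t == "" for t in self.tokens):
            raise InvalidInputError("TokenSequence may not contain empty tokens")

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self):
        return iter(self.tokens)

    def as_text(self) -> str:
        """Tokens rejoined with single spaces (input for character/sequence measures)."""
        return " ".join(self.tokens)

    def as_set(self) -> frozenset[str]:
        return frozenset(self.tokens)


@lru_cache(maxsize=1)
def stopwords() -> frozenset[str]:
    """The frozen English stopword list bundled with the package."""
    text = resources.files("clinsts.data").joinpath("stopwords_en.txt").read_text("utf-8")
    return frozenset(w for w in text.split() if w)


# Treebank-style tokenization rules, specialised to already-lowercased text.
_TB_RULES: list[tuple[re.Pattern[str], str]] = [
    (re.compile(r'([\[\](){}<>;@#$%&!?"*+=|~^“”])'), r" \1 "),
    (re.compile(r"(,)(?!\d)"), r" \1 "),
    (re.compile(r"(?<!\d)(,)"), r" \1 "),
    (re.compile(r"(:)(?!\d)"), r" \1 "),
    (re.compile(r"(?<!\d)(:)"), r" \1 "),
    (re.compile(r"\.\.\."), r" ... "),
    (re.compile(r"(\.)\s*$"), r" \1"),            # sentence-final period
    (re.compile(r"(\.)(\s)"), r" \1\2"),           # period before a space
    (re.compile(r"([^\W\d_])('s|'re|'ve|'ll|'d|'m)\b"), r"\1 \2"),
    (re.compile(r"([^\W\d_])(n't)\b"), r"\1 \2"),
]


def tokenize(text: str, remove_stop: bool = False) -> TokenSequence:
    """Tokenize a normalized sentence with Treebank-style rules.

    With ``remove_stop``, stopwords and punctuation-only tokens are dropped;
    a sentence made entirely of stopwords legitimately yields an empty
    sequence, and downstream measures handle that case explicitly.
    """
    out = text
    for pattern, repl in _TB_RULES:
        out = pattern.sub(repl, out)
    toks = [t for t in out.split() if t]
    if remove_stop:
        stop = stopwords()
        toks = [
            t for t in toks
            if t not in stop and not all(c in PUNCTUATION_SET for c in t)
        ]
    return TokenSequence(tuple(toks), stop_filtered=remove_stop)


def preprocess(text: str, remove_stop: bool = True) -> TokenSequence:
    """Convenience composition ``tokenize(normalize(text))``."""
    return tokenize(normalize(text), remove_stop=remove_stop)
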