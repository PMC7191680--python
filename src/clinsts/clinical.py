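"""Entity-overlap and number similarity features.

Clinical sentences carry named entities (problems, medications, treatments)
whose overlap is a strong similarity signal.  A full clinical NLP pipeline
(CLAMP-style concept extraction mapped to UMLS CUIs) is out of scope here;
instead, two extractor modes are provided:

* **dictionary mode** — a bundled phrase → CUI lexicon matched
  longest-phrase-first over the token sequence;
* **import mode** — pre-computed annotations (pair id, side, CUI list) read
  from a TSV sidecar, so output of an external concept extractor can be
  plugged in unchanged.

Numbers get their own feature: digits are normalized to their word form
("24" becomes "twenty-four"); if both sentences contain numbers the
similarity is a transform of the Word Mover's Distance between the two
number-word sequences, if neither does it is 1, and if exactly one does it
is 0.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping
from importlib import resources
from pathlib import Path

from .errors import InvalidInputError, ParseError, StateError
from .semantic import EmbeddingBackend, word_movers_distance
from .textprep import TokenSequence

__all__ = [
    "DictionaryExtractor",
    "AnnotationImportExtractor",
    "load_bundled_lexicon",
    "extract_concepts",
    "entity_similarity",
    "extract_numbers",
    "number_similarity",
    "int_to_words",
]


def load_bundled_lexicon() -> dict[str, str]:
    """The small phrase → CUI lexicon shipped with the package."""
    text = resources.files("clinsts.data").joinpath("lexicon.tsv").read_text("utf-8")
    return _parse_lexicon(text.splitlines())


def load_lexicon(path: str | Path) -> dict[str, str]:
    """Read a two-column ``phrase TAB cui`` lexicon file."""
    return _parse_lexicon(Path(path).read_text("utf-8").splitlines())


def _parse_lexicon(lines: Iterable[str]) -> dict[str, str]:
    lex: dict[str, str] = {}
    for i, line in enumerate(lines, start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != 2 or not parts[0].strip() or not parts[1].strip():
            raise ParseError("expected 'phrase<TAB>cui'", line=i)
        lex[parts[0].strip().lower()] = parts[1].strip()
    return lex


class DictionaryExtractor:
    """Concept extraction by longest-match-first lexicon lookup.

    Phrases are matched against the token sequence left to right; at each
    position the longest matching lexicon phrase wins and its tokens are
    consumed, so "abdominal pain" shadows a bare "pain" entry.
    """

    name = "dictionary"

    def __init__(self, lexicon: Mapping[str, str] | None = None):
        lex = dict(lexicon) if lexicon is not None else load_bundled_lexicon()
        if not lex:
            raise InvalidInputError("dictionary extractor requires a non-empty lexicon")
        self._phrases: dict[tuple[str, ...], str] = {
            tuple(phrase.split()): cui for phrase, cui in lex.items()
        }
        self._max_len = max(len(p) for p in self._phrases)

    def extract(self, tokens: TokenSequence | Iterable[str]) -> frozenset[str]:
        toks = tuple(tokens)
        found: set[str] = set()
        i = 0
        while i < len(toks):
            for width in range(min(self._max_len, len(toks) - i), 0, -1):
                cui = self._phrases.get(toks[i : i + width])
                if cui is not None:
                    found.add(cui)
                    i += width
                    break
            else:
                i += 1
        return frozenset(found)

    def fingerprint(self) -> dict:
        return {"extractor": self.name, "n_phrases": len(self._phrases)}


class AnnotationImportExtractor:
    """Concept sets imported from a pre-computed annotation sidecar.

    The sidecar is a TSV with rows ``pair_id TAB side(a|b) TAB
    comma-separated CUIs``, the natural export format of an external
    concept-extraction pipeline run once over the corpus.
    """

    name = "import"

    def __init__(self, path: str | Path):
        path = Path(path)
        if not path.exists():
            raise StateError(f"annotation file not found: {path}")
        self._table: dict[tuple[str, str], frozenset[str]] = {}
        for i, line in enumerate(path.read_text("utf-8").splitlines(), start=1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3 or parts[1] not in ("a", "b"):
                raise ParseError("expected 'pair_id<TAB>a|b<TAB>cui,cui,...'", line=i)
            cuis = frozenset(c.strip() for c in parts[2].split(",") if c.strip())
            self._table[(parts[0], parts[1])] = cuis

    def concepts_for(self, pair_id: str, side: str) -> frozenset[str]:
        return self._table.get((pair_id, side), frozenset())

    def extract(self, tokens) -> frozenset[str]:
        raise StateError(
            "import-mode extractor annotates by pair id, not by token sequence; "
            "use concepts_for(pair_id, side)"
        )

    def fingerprint(self) -> dict:
        return {"extractor": self.name, "n_rows": len(self._table)}


def extract_concepts(extractor, tokens: TokenSequence | Iterable[str]) -> frozenset[str]:
    """Concept identifiers found in *tokens* by the given extractor."""
    return extractor.extract(tokens)


def entity_similarity(cx: Iterable[str], cy: Iterable[str]) -> float:
    """Shared CUIs over the larger concept set: |cx ∩ cy| / max(|cx|, |cy|).

    Two sentences without any concept are treated as trivially agreeing (1);
    a concept-bearing sentence against a concept-free one scores 0.
    """
    sx, sy = frozenset(cx), frozenset(cy)
    if not sx and not sy:
        return 1.0
    if not sx or not sy:
        return 0.0
    return len(sx & sy) / max(len(sx), len(sy))


# ---------------------------------------------------------------------------
# Numbers
# ---------------------------------------------------------------------------

_UNITS = [
    "zero", "one", "two", "three", "four", "five", "six", "seven", "eight",
    "nine", "ten", "eleven", "twelve", "thirteen", "fourteen", "fifteen",
    "sixteen", "seventeen", "eighteen", "nineteen",
]
_TENS = ["", "", "twenty", "thirty", "forty", "fifty", "sixty", "seventy",
         "eighty", "ninety"]

#: Closed list of spelled-out numbers recognized as number tokens.
NUMBER_WORDS = frozenset(_UNITS) | frozenset(t for t in _TENS if t) | {"hundred"}

_INT_RE = re.compile(r"^\d+$")
_DECIMAL_RE = re.compile(r"^\d+\.\d+$")


def int_to_words(n: int) -> str:
    """Spell out a non-negative integer < 1,000,000 ("24" → "twenty-four")."""
    if n < 0 or n >= 1_000_000:
        raise InvalidInputError("int_to_words handles 0 <= n < 1,000,000")
    if n < 20:
        return _UNITS[n]
    if n < 100:
        tens, unit = divmod(n, 10)
        return _TENS[tens] + (f"-{_UNITS[unit]}" if unit else "")
    if n < 1000:
        hundreds, rest = divmod(n, 100)
        head = f"{_UNITS[hundreds]} hundred"
        return head + (f" {int_to_words(rest)}" if rest else "")
    thousands, rest = divmod(n, 1000)
    head = f"{int_to_words(thousands)} thousand"
    return head + (f" {int_to_words(rest)}" if rest else "")


def _number_token_to_words(token: str) -> str | None:
    tok = token.lower()
    if _INT_RE.match(tok):
        return int_to_words(int(tok))
    if _DECIMAL_RE.match(tok):
        whole, frac = tok.split(".")
        frac_words = " ".join(_UNITS[int(d)] for d in frac)
        return f"{int_to_words(int(whole))} point {frac_words}"
    if tok in NUMBER_WORDS:
        return tok
    return None


def extract_numbers(tokens: TokenSequence | Iterable[str]) -> TokenSequence:
    """The number tokens of a sentence, each converted to its word form.

    Detects integer and decimal digit tokens plus a closed list of
    spelled-out numbers; order and multiplicity are preserved.
    """
    words = []
    for tok in tokens:
        w = _number_token_to_words(tok)
        if w is not None:
            words.append(w)
    return TokenSequence(tuple(words))


def number_similarity(
    a: TokenSequence | Iterable[str],
    b: TokenSequence | Iterable[str],
    backend: EmbeddingBackend,
) -> float:
    """Similarity between the numbers mentioned by the two sentences.

    Neither sentence contains numbers → 1; exactly one does → 0; both do →
    ``1 / (1 + WMD)`` over the extracted number-word sequences, so identical
    number mentions score 1 and increasingly distant ones decay toward 0.
    """
    na, nb = extract_numbers(a), extract_numbers(b)
    if not len(na) and not len(nb):
        return 1.0
    if not len(na) or not len(nb):
        return 0.0
    return 1.0 / (1.0 + word_movers_distance(backend, na, nb))
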