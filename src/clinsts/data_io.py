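"""Sentence-pair dataset I/O, train/validation splitting, and synthesis.

The on-disk format is the STS-benchmark style tab-separated layout
``sentence_a TAB sentence_b TAB score`` (UTF-8, no quoting, Unix newlines),
with the score column optional at prediction time.  Scores live on the 0-5
scale used by clinical STS annotation guidelines: 0 means completely
dissimilar, 5 means the sentences mean the same thing, and real corpora
concentrate more than half of the pairs between 2 and 4.

Because the real clinical dataset is distribution-restricted, this module
also provides a synthetic generator that emulates its structure: pairs are
built from a bank of clinical-style sentence templates, a similarity band
0-5 is sampled per pair, and increasingly aggressive perturbations (synonym
swaps, token drops, clause substitutions, number changes, unrelated
pairings) produce sentence pairs whose surface and semantic overlap decay
with the band.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import ConfigError, InvalidInputError, ParseError
from .templates import NUMBER_CHOICES, SYNONYMS, TEMPLATE_BANK, Template

__all__ = [
    "SentencePair",
    "read_pairs",
    "write_pairs",
    "split_train_validation",
    "SyntheticConfig",
    "generate_pairs",
]


@dataclass(frozen=True)
class SentencePair:
    """Two raw sentences plus an optional gold similarity in [0, 5]."""

    pair_id: str
    text_a: str
    text_b: str
    gold_score: float | None = None

    def __post_init__(self) -> None:
        if self.gold_score is not None and not 0.0 <= self.gold_score <= 5.0:
            raise InvalidInputError(
                f"gold score {self.gold_score} outside [0, 5] for pair {self.pair_id}"
            )


def _pair_id(index: int) -> str:
    return f"p{index:04d}"


def read_pairs(path: str | Path) -> list[SentencePair]:
    """Read a tab-separated sentence-pair file.

    Lines carry either two columns (unlabeled) or three (with gold score);
    blank lines are skipped.  Malformed lines raise :class:`ParseError`
    with their line number.
    """
    pairs: list[SentencePair] = []
    for lineno, line in enumerate(
        Path(path).read_text("utf-8").splitlines(), start=1
    ):
        if not line.strip():
            continue
        cols = line.split("\t")
        if len(cols) == 2:
            a, b = cols
            score = None
        elif len(cols) == 3:
            a, b = cols[0], cols[1]
            try:
                score = float(cols[2])
            except ValueError as exc:
                raise ParseError(f"unparseable score {cols[2]!r}", line=lineno) from exc
            if not 0.0 <= score <= 5.0:
                raise ParseError(f"score {score} outside [0, 5]", line=lineno)
        else:
            raise ParseError(
                f"expected 2 or 3 tab-separated columns, found {len(cols)}",
                line=lineno,
            )
        if not a.strip() or not b.strip():
            raise ParseError("empty sentence", line=lineno)
        pairs.append(SentencePair(_pair_id(len(pairs) + 1), a, b, score))
    return pairs


def write_pairs(pairs: list[SentencePair], path: str | Path) -> None:
    """Write pairs in the tab-separated layout; round-trips through :func:`read_pairs`."""
    lines = []
    for p in pairs:
        for text in (p.text_a, p.text_b):
            if "\t" in text or "\n" in text:
                raise InvalidInputError(
                    f"pair {p.pair_id}: sentences may not contain tabs or newlines"
                )
        if p.gold_score is None:
            lines.append(f"{p.text_a}\t{p.text_b}")
        else:
            lines.append(f"{p.text_a}\t{p.text_b}\t{p.gold_score!r}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), "utf-8")


def split_train_validation(
    pairs: list[SentencePair], seed: int, train_fraction: float = 0.8
) -> tuple[list[SentencePair], list[SentencePair]]:
    """Seeded shuffle, then split at *train_fraction* (4/5 by default).

    A 750-pair labeled set yields the conventional 600-pair training and
    150-pair validation partition.  The two halves are disjoint and
    exhaustive, and membership is fully determined by the seed.
    """
    if len(pairs) < 2:
        raise InvalidInputError("need at least 2 pairs to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pairs))
    n_train = int(len(pairs) * train_fraction)
    train = [pairs[i] for i in order[:n_train]]
    val = [pairs[i] for i in order[n_train:]]
    return train, val


# ---------------------------------------------------------------------------
# Synthetic generation
# ---------------------------------------------------------------------------

#: Probability of each similarity band 0..5; band 3 dominates so that, with
#: the +-0.25 jitter, more than half of all gold scores land inside [2, 4].
DEFAULT_SCORE_DISTRIBUTION: dict[int, float] = {
    0: 0.08, 1: 0.12, 2: 0.20, 3: 0.34, 4: 0.20, 5: 0.06,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Configuration of the synthetic sentence-pair generator."""

    n_pairs: int = 750
    seed: int = 0
    score_distribution: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_DISTRIBUTION)
    )
    jitter: float = 0.25
    templates: tuple[Template, ...] = TEMPLATE_BANK
    synonyms: dict[str, str] = field(default_factory=lambda: dict(SYNONYMS))

    def __post_init__(self) -> None:
        if self.n_pairs <= 0:
            raise ConfigError("n_pairs must be positive")
        if not self.templates:
            raise ConfigError("template bank is empty")
        if set(self.score_distribution) != set(range(6)):
            raise ConfigError("score_distribution must cover bands 0..5")
        total = sum(self.score_distribution.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"score_distribution sums to {total}, expected 1")


def _instantiate(tpl: Template, rng: np.random.Generator) -> list[list[str]]:
    """Fill number placeholders; return the sentence as clause token-lists."""
    clauses = []
    for clause in tpl.clauses:
        toks = []
        for tok in clause.split():
            if tok == "<n>":
                toks.append(str(rng.choice(NUMBER_CHOICES)))
            else:
                toks.append(tok)
        clauses.append(toks)
    return clauses


def _render(clauses: list[list[str]]) -> str:
    return ", ".join(" ".join(c) for c in clauses)


def _synonym_swap(clauses, synonyms, rng, k):
    spots = [
        (i, j)
        for i, c in enumerate(clauses)
        for j, tok in enumerate(c)
        if tok in synonyms
    ]
    if spots:
        take = min(k, len(spots))
        for idx in rng.choice(len(spots), size=take, replace=False):
            i, j = spots[idx]
            clauses[i][j] = synonyms[clauses[i][j]]
    return clauses


def _token_drop(clauses, rng, k=1):
    for _ in range(k):
        droppable = [
            (i, j)
            for i, c in enumerate(clauses)
            if len(c) > 3
            for j, tok in enumerate(c)
            if not tok.isdigit()
        ]
        if not droppable:
            break
        i, j = droppable[rng.integers(len(droppable))]
        del clauses[i][j]
    return clauses


def _number_alter(clauses, rng):
    spots = [(i, j) for i, c in enumerate(clauses) for j, t in enumerate(c) if t.isdigit()]
    if spots:
        i, j = spots[rng.integers(len(spots))]
        current = clauses[i][j]
        options = [str(n) for n in NUMBER_CHOICES if str(n) != current]
        clauses[i][j] = options[rng.integers(len(options))]
    return clauses


def _other_template(tpl: Template, templates, rng, same_register: bool) -> Template:
    pool = [
        t for t in templates
        if (t.register == tpl.register) == same_register and t is not tpl
    ]
    if not pool:  # degenerate custom bank: fall back to any other template
        pool = [t for t in templates if t is not tpl] or [tpl]
    return pool[rng.integers(len(pool))]


def _perturb(tpl, clauses_a, band, cfg, rng):
    """Derive sentence B from sentence A according to the similarity band."""
    clauses = [list(c) for c in clauses_a]
    if band == 5:
        return clauses
    if band == 4:
        return _synonym_swap(clauses, cfg.synonyms, rng, k=int(rng.integers(1, 3)))
    if band == 3:
        clauses = _synonym_swap(clauses, cfg.synonyms, rng, k=2)
        if len(clauses) > 1 and rng.random() < 0.5:
            rng.shuffle(clauses)
        else:
            clauses = _token_drop(clauses, rng, k=int(rng.integers(1, 3)))
        return clauses
    if band == 2:
        donor = _instantiate(_other_template(tpl, cfg.templates, rng, True), rng)
        victim = int(rng.integers(len(clauses)))
        clauses[victim] = donor[int(rng.integers(len(donor)))]
        clauses = _synonym_swap(clauses, cfg.synonyms, rng, k=1)
        clauses = _token_drop(clauses, rng, k=1)
        if rng.random() < 0.5:
            clauses = _number_alter(clauses, rng)
        return clauses
    if band == 1:
        return _instantiate(_other_template(tpl, cfg.templates, rng, True), rng)
    return _instantiate(_other_template(tpl, cfg.templates, rng, False), rng)


def generate_pairs(cfg: SyntheticConfig) -> list[SentencePair]:
    """Generate a reproducible synthetic clinical sentence-pair dataset.

    For each pair a similarity band is drawn from ``cfg.score_distribution``;
    sentence A instantiates a random template, sentence B is a
    band-dependent perturbation of A (band 5: identical; band 0: an
    unrelated template from a different register).  The gold score is the
    band value plus uniform jitter of half-width ``cfg.jitter``, clipped to
    [0, 5], mimicking averaged two-annotator scores.
    """
    rng = np.random.default_rng(cfg.seed)
    bands = list(range(6))
    probs = np.array([cfg.score_distribution[b] for b in bands])
    pairs: list[SentencePair] = []
    for i in range(cfg.n_pairs):
        band = int(rng.choice(bands, p=probs))
        tpl = cfg.templates[int(rng.integers(len(cfg.templates)))]
        clauses_a = _instantiate(tpl, rng)
        clauses_b = _perturb(tpl, clauses_a, band, cfg, rng)
        gold = float(np.clip(band + rng.uniform(-cfg.jitter, cfg.jitter), 0.0, 5.0))
        pairs.append(
            SentencePair(_pair_id(i + 1), _render(clauses_a), _render(clauses_b), gold)
        )
    return pairs
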