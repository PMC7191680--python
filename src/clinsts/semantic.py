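"""Embedding backends, cosine similarity, and Word Mover's Distance.

The semantic feature is the cosine similarity between sentence vectors.  A
pre-trained biomedical sent2vec model (e.g. BioSentVec, 700 dimensions) can
be plugged in from a local path; the default backend is a deterministic
hash-projection embedder that needs no model file, so the whole pipeline can
be built and tested offline.  Word vectors from the active backend also
drive the Word Mover's Distance used by the number-similarity feature.
"""

from __future__ import annotations

import hashlib
from abc import ABC, abstractmethod
from collections import Counter
from collections.abc import Iterable

import numpy as np
from scipy.optimize import linprog

from .errors import InvalidInputError, StateError

DEFAULT_FIXTURE_DIM = 32
DEFAULT_FIXTURE_SEED = 0


class EmbeddingBackend(ABC):
    """Deterministic sentence/word embedder: identical input, identical vector."""

    name: str
    dim: int

    @abstractmethod
    def embed_sentence(self, sentence: str) -> np.ndarray:
        """Embed a (pre-processed) sentence into a ``dim``-vector."""

    @abstractmethod
    def embed_token(self, token: str) -> np.ndarray:
        """Embed a single token into a ``dim``-vector."""

    def fingerprint(self) -> dict:
        return {"backend": self.name, "dim": self.dim}


class HashProjectionEmbedder(EmbeddingBackend):
    """Deterministic embedder mapping each token to a seeded pseudo-random unit vector.

    The vector for a token is drawn from a PCG64 generator seeded with a
    BLAKE2 digest of the token and the embedder seed, then normalized to unit
    length; a sentence embeds as the mean of its whitespace-token vectors.
    Repeated whitespace therefore cannot change a sentence's vector.  An
    empty (all-whitespace) sentence embeds as the zero vector.
    """

    def __init__(self, dim: int = DEFAULT_FIXTURE_DIM, seed: int = DEFAULT_FIXTURE_SEED):
        if dim <= 0:
            raise InvalidInputError("embedding dim must be positive")
        self.dim = int(dim)
        self.seed = int(seed)
        self.name = f"hash-projection-{self.dim}-{self.seed}"
        self._cache: dict[str, np.ndarray] = {}

    def embed_token(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}\x00{token}".encode("utf-8"), digest_size=8
            ).digest()
            rng = np.random.Generator(np.random.PCG64(int.from_bytes(digest, "little")))
            raw = rng.standard_normal(self.dim)
            vec = raw / np.linalg.norm(raw)
            self._cache[token] = vec
        return vec.copy()

    def embed_sentence(self, sentence: str) -> np.ndarray:
        tokens = sentence.split()
        if not tokens:
            return np.zeros(self.dim)
        return np.mean([self.embed_token(t) for t in tokens], axis=0)

    def fingerprint(self) -> dict:
        return {"backend": self.name, "dim": self.dim, "seed": self.seed}


class Sent2VecBackend(EmbeddingBackend):
    """Optional backend over a pre-trained sent2vec model (e.g. BioSentVec).

    The model is loaded lazily from a user-supplied path.  If the ``sent2vec``
    package or the model file is unavailable the backend raises a
    :class:`StateError`; it never falls back silently.  Word vectors for the
    Word Mover's Distance come from a hash-projection embedder so that
    out-of-vocabulary tokens still embed deterministically.
    """

    def __init__(self, model_path: str, dim: int = 700,
                 oov_seed: int = DEFAULT_FIXTURE_SEED):
        self.model_path = model_path
        self.dim = int(dim)
        self.name = "sent2vec"
        self._model = None
        self._oov = HashProjectionEmbedder(dim=self.dim, seed=oov_seed)

    def _load(self):
        if self._model is None:
            try:
                import sent2vec  # type: ignore
            except ImportError as exc:
                raise StateError(
                    "the sent2vec package is not installed; install it and "
                    "supply a model path, or use the hash-projection backend"
                ) from exc
            model = sent2vec.Sent2vecModel()
            model.load_model(self.model_path)
            self._model = model
        return self._model

    def embed_sentence(self, sentence: str) -> np.ndarray:
        model = self._load()
        return np.asarray(model.embed_sentence(sentence)[0], dtype=float)

    def embed_token(self, token: str) -> np.ndarray:
        return self._oov.embed_token(token)

    def fingerprint(self) -> dict:
        return {"backend": self.name, "dim": self.dim, "model_path": self.model_path}


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine of two vectors, clipped into [0, 1].

    Negative cosines are truncated to 0 so the feature shares the [0, 1]
    range of every other similarity; a zero vector on either side gives 0.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise InvalidInputError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.clip(u @ v / (nu * nv), 0.0, 1.0))


def word_movers_distance(
    backend: EmbeddingBackend,
    tokens_a: Iterable[str],
    tokens_b: Iterable[str],
) -> float:
    """Minimum-cost transport between two token bags in embedding space.

    Each sequence becomes a normalized bag-of-words distribution over its
    unique tokens; the ground cost between tokens is the Euclidean distance
    between their word vectors.  Identical multisets are distance 0, and the
    1-token-vs-1-token case reduces to the plain Euclidean distance.
    """
    ta, tb = list(tokens_a), list(tokens_b)
    if not ta or not tb:
        raise InvalidInputError("word_movers_distance requires non-empty sequences")
    ca, cb = Counter(ta), Counter(tb)
    if ca == cb:
        return 0.0
    ua, ub = sorted(ca), sorted(cb)
    p = np.array([ca[t] for t in ua], dtype=float)
    q = np.array([cb[t] for t in ub], dtype=float)
    p /= p.sum()
    q /= q.sum()
    va = np.stack([backend.embed_token(t) for t in ua])
    vb = np.stack([backend.embed_token(t) for t in ub])
    cost = np.linalg.norm(va[:, None, :] - vb[None, :, :], axis=2)
    n, m = len(p), len(q)
    if n == 1:
        return float(cost[0] @ q)
    if m == 1:
        return float(p @ cost[:, 0])
    # transportation LP: row marginals p, column marginals q
    a_eq = np.zeros((n + m, n * m))
    for i in range(n):
        a_eq[i, i * m : (i + 1) * m] = 1.0
    for j in range(m):
        a_eq[n + j, j::m] = 1.0
    res = linprog(
        cost.ravel(), A_eq=a_eq[:-1], b_eq=np.concatenate([p, q])[:-1],
        bounds=(0, None), method="highs",
    )
    if not res.success:  # pragma: no cover - the balanced LP is always feasible
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)
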