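"""Feature assembly and the three regressors.

The similarity of a sentence pair is predicted on the 0-5 scale by

* a **random forest** over a 14-dimensional vector of engineered similarity
  features drawn from five families — token (5), character (2), sequence
  (4), semantic (1) and entity (2);
* an **encoder network**: a fully connected net over the two sentence
  embeddings composed as ``concat(v1, v2, |v1 - v2|, v1 * v2)``, with hidden
  layers of 480, 240 and 80 rectified units, trained by SGD on mean squared
  error with L2 weight decay and dropout, early-stopped on validation loss
  and checkpointed at the best validation Pearson;
* a **stacking ensemble**: ordinary least squares over the component models'
  validation-set predictions.

All predictions are clipped to [0, 5].  Model bundles carry a fingerprint of
the feature/backend configuration they were trained under and refuse inputs
produced under a different configuration.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from typing import Sequence

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from . import lexical
from .clinical import (
    AnnotationImportExtractor,
    DictionaryExtractor,
    entity_similarity,
    number_similarity,
)
from .data_io import SentencePair
from .errors import InvalidInputError, StateError, TrainingError
from .lexical import (
    AlignmentScoring,
    DEFAULT_JARO_THRESHOLD,
    DEFAULT_QGRAM_SIZES,
    IdfModel,
)
from .semantic import EmbeddingBackend, HashProjectionEmbedder, cosine_similarity
from .textprep import normalize, tokenize

logger = logging.getLogger(__name__)

SCORE_RANGE = (0.0, 5.0)

#: Frozen slot order of the engineered feature vector.
FEATURE_NAMES: tuple[str, ...] = (
    "jaccard", "generalized_jaccard", "dice", "ochiai", "tfidf",
    "qgram3", "qgram4",
    "bag", "levenshtein", "needleman_wunsch", "smith_waterman",
    "embedding_cosine",
    "entity_sim", "number_sim",
)

#: Feature families and their slots (5 + 2 + 4 + 1 + 2 = 14).
FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "token": ("jaccard", "generalized_jaccard", "dice", "ochiai", "tfidf"),
    "character": ("qgram3", "qgram4"),
    "sequence": ("bag", "levenshtein", "needleman_wunsch", "smith_waterman"),
    "semantic": ("embedding_cosine",),
    "entity": ("entity_sim", "number_sim"),
}


@dataclass(frozen=True)
class FeatureVector:
    """The ordered 14-slot similarity feature vector of one sentence pair."""

    jaccard: float
    generalized_jaccard: float
    dice: float
    ochiai: float
    tfidf: float
    qgram3: float
    qgram4: float
    bag: float
    levenshtein: float
    needleman_wunsch: float
    smith_waterman: float
    embedding_cosine: float
    entity_sim: float
    number_sim: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v) or not 0.0 <= v <= 1.0:
                raise InvalidInputError(f"feature {name}={v} outside [0, 1]")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)

    @staticmethod
    def names() -> tuple[str, ...]:
        return FEATURE_NAMES


assert tuple(f.name for f in dc_fields(FeatureVector)) == FEATURE_NAMES


class FeatureContext:
    """Everything feature extraction needs: idf model, backend, extractor.

    Built once from the training split (the idf weights must never see
    validation or test sentences) and shared by all downstream models; its
    fingerprint ties trained bundles to the exact configuration.
    """

    def __init__(
        self,
        backend: EmbeddingBackend | None = None,
        extractor: DictionaryExtractor | AnnotationImportExtractor | None = None,
        qgram_sizes: tuple[int, int] = DEFAULT_QGRAM_SIZES,
        jaro_threshold: float = DEFAULT_JARO_THRESHOLD,
        scoring: AlignmentScoring | None = None,
    ):
        self.backend = backend if backend is not None else HashProjectionEmbedder()
        self.extractor = extractor if extractor is not None else DictionaryExtractor()
        self.qgram_sizes = tuple(qgram_sizes)
        self.jaro_threshold = jaro_threshold
        self.scoring = scoring if scoring is not None else AlignmentScoring()
        self.idf_model = IdfModel()
        self._cache: dict[str, tuple] = {}

    def fit_idf(self, pairs: Sequence[SentencePair]) -> "FeatureContext":
        """Fit idf weights on the (deduplicated) sentences of the training pairs."""
        seen: dict[str, list[str]] = {}
        for p in pairs:
            for text in (p.text_a, p.text_b):
                if text not in seen:
                    seen[text] = list(tokenize(normalize(text), remove_stop=True))
        self.idf_model.fit(seen.values())
        return self

    @property
    def ready(self) -> bool:
        return self.idf_model.fitted

    def fingerprint(self) -> str:
        payload = {
            "features": FEATURE_NAMES,
            "qgram_sizes": self.qgram_sizes,
            "jaro_threshold": self.jaro_threshold,
            "scoring": (self.scoring.match, self.scoring.mismatch, self.scoring.gap),
            "backend": self.backend.fingerprint(),
            "extractor": self.extractor.fingerprint(),
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode("utf-8")).hexdigest()

    def _sentence(self, text: str):
        cached = self._cache.get(text)
        if cached is None:
            norm = normalize(text)
            toks_all = tokenize(norm, remove_stop=False)
            toks = tokenize(norm, remove_stop=True)
            cached = (norm, toks_all, toks, toks.as_text())
            self._cache[text] = cached
        return cached


def extract_features(pair: SentencePair, ctx: FeatureContext) -> FeatureVector:
    """Compute the 14 similarity features of one sentence pair."""
    if not ctx.ready:
        raise StateError("FeatureContext.fit_idf must run before extract_features")
    _, all_a, toks_a, str_a = ctx._sentence(pair.text_a)
    _, all_b, toks_b, str_b = ctx._sentence(pair.text_b)
    set_a, set_b = toks_a.as_set(), toks_b.as_set()

    if isinstance(ctx.extractor, AnnotationImportExtractor):
        concepts_a = ctx.extractor.concepts_for(pair.pair_id, "a")
        concepts_b = ctx.extractor.concepts_for(pair.pair_id, "b")
    else:
        concepts_a = ctx.extractor.extract(all_a)
        concepts_b = ctx.extractor.extract(all_b)

    q3, q4 = ctx.qgram_sizes
    emb_a = ctx.backend.embed_sentence(str_a)
    emb_b = ctx.backend.embed_sentence(str_b)
    return FeatureVector(
        jaccard=lexical.jaccard(set_a, set_b),
        generalized_jaccard=lexical.generalized_jaccard(
            set_a, set_b, threshold=ctx.jaro_threshold
        ),
        dice=lexical.dice(set_a, set_b),
        ochiai=lexical.ochiai(set_a, set_b),
        tfidf=lexical.tfidf_cosine(toks_a, toks_b, ctx.idf_model),
        qgram3=lexical.qgram_similarity(str_a, str_b, q3),
        qgram4=lexical.qgram_similarity(str_a, str_b, q4),
        bag=lexical.bag_similarity(str_a, str_b),
        levenshtein=lexical.levenshtein_similarity(str_a, str_b),
        needleman_wunsch=lexical.needleman_wunsch_similarity(str_a, str_b, ctx.scoring),
        smith_waterman=lexical.smith_waterman_similarity(str_a, str_b, ctx.scoring),
        embedding_cosine=cosine_similarity(emb_a, emb_b),
        entity_sim=entity_similarity(concepts_a, concepts_b),
        number_sim=number_similarity(all_a, all_b, ctx.backend),
    )


def feature_matrix(pairs: Sequence[SentencePair], ctx: FeatureContext) -> np.ndarray:
    """Stack :func:`extract_features` over pairs into an (n, 14) array."""
    return np.array([extract_features(p, ctx).to_array() for p in pairs])


def _clip_scores(y: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(y, dtype=float), *SCORE_RANGE)


def _check_scores(scores: Sequence[float]) -> np.ndarray:
    y = np.asarray(scores, dtype=float)
    if y.size and (y.min() < SCORE_RANGE[0] or y.max() > SCORE_RANGE[1]):
        raise InvalidInputError("training scores must lie in [0, 5]")
    return y


# ---------------------------------------------------------------------------
# Model bundles
# ---------------------------------------------------------------------------

@dataclass
class ModelBundle:
    """A fitted model plus the configuration fingerprint it was trained under."""

    kind: str
    predictor: object
    fingerprint: str | None
    seed: int | None = None
    meta: dict = field(default_factory=dict)

    def _check(self, fingerprint: str | None) -> None:
        if (
            self.fingerprint is not None
            and fingerprint is not None
            and fingerprint != self.fingerprint
        ):
            raise InvalidInputError(
                "configuration fingerprint mismatch between training and prediction"
            )

    def predict(self, X: np.ndarray, fingerprint: str | None = None) -> np.ndarray:
        """Predict scores (clipped to [0, 5]) for pre-assembled model inputs."""
        self._check(fingerprint)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise InvalidInputError("expected a 2-D input matrix")
        if X.shape[0] == 0:
            return np.zeros(0)
        if self.kind == "random_forest":
            raw = self.predictor.predict(X)
        elif self.kind == "encoder":
            raw = self.predictor.forward(X)
        elif self.kind == "ensemble":
            w, b, keep = self.predictor
            if X.shape[1] != self.meta["n_components_original"]:
                raise InvalidInputError(
                    f"ensemble expects {self.meta['n_components_original']} "
                    f"component columns, got {X.shape[1]}"
                )
            raw = X[:, keep] @ w + b
        else:  # pragma: no cover
            raise InvalidInputError(f"unknown bundle kind {self.kind!r}")
        return _clip_scores(raw)


def train_random_forest(
    features: np.ndarray | Sequence[FeatureVector],
    scores: Sequence[float],
    seed: int = 0,
    n_estimators: int = 500,
    fingerprint: str | None = None,
) -> ModelBundle:
    """Fit the random-forest regressor on engineered feature vectors."""
    if features is not None and len(features) and isinstance(features[0], FeatureVector):
        X = np.array([f.to_array() for f in features])
    else:
        X = np.asarray(features, dtype=float)
    y = _check_scores(scores)
    if X.shape[0] < 2:
        raise InvalidInputError("need at least 2 training pairs")
    forest = RandomForestRegressor(
        n_estimators=n_estimators, random_state=seed, n_jobs=1
    )
    forest.fit(X, y)
    return ModelBundle(
        kind="random_forest",
        predictor=forest,
        fingerprint=fingerprint,
        seed=seed,
        meta={"n_features": X.shape[1], "n_estimators": n_estimators},
    )


# ---------------------------------------------------------------------------
# Encoder network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EncoderConfig:
    """Hyper-parameters of the encoder network.

    The architecture and optimizer settings (three hidden layers of 480, 240
    and 80 units, SGD at learning rate 1e-4, MSE loss, dropout 0.5, early
    stopping after 200 epochs without validation-loss improvement) are fixed
    defaults; L2 strength, batch size and the epoch cap are tunable.
    """

    hidden_sizes: tuple[int, int, int] = (480, 240, 80)
    learning_rate: float = 1e-4
    dropout: float = 0.5
    l2_lambda: float = 1e-4
    patience_epochs: int = 200
    seed: int = 0
    batch_size: int = 32
    max_epochs: int = 1000
    elementwise_product: bool = True

    def __post_init__(self) -> None:
        if len(self.hidden_sizes) != 3:
            raise InvalidInputError("hidden_sizes must have exactly 3 layers")
        if self.learning_rate <= 0:
            raise InvalidInputError("learning_rate must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise InvalidInputError("dropout must be in [0, 1)")


def encoder_inputs(
    pairs: Sequence[SentencePair],
    backend: EmbeddingBackend,
    elementwise_product: bool = True,
) -> np.ndarray:
    """Compose pair inputs ``concat(v1, v2, |v1 - v2|, v1 * v2)``.

    With ``elementwise_product`` (default) the fourth block is the
    element-wise product, giving input length 4 x dim; with the scalar
    variant the fourth block is the single scalar dot product.
    """
    rows = []
    for p in pairs:
        v1 = backend.embed_sentence(_preprocessed_text(p.text_a))
        v2 = backend.embed_sentence(_preprocessed_text(p.text_b))
        tail = v1 * v2 if elementwise_product else np.array([v1 @ v2])
        rows.append(np.concatenate([v1, v2, np.abs(v1 - v2), tail]))
    return np.array(rows) if rows else np.zeros((0, 0))


_PREP_CACHE: dict[str, str] = {}


def _preprocessed_text(text: str) -> str:
    out = _PREP_CACHE.get(text)
    if out is None:
        out = tokenize(normalize(text), remove_stop=True).as_text()
        _PREP_CACHE[text] = out
    return out


class _EncoderNet:
    """Plain-numpy fully connected regressor used by the encoder bundle."""

    def __init__(self, sizes: Sequence[int], rng: np.random.Generator):
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for fan_in, fan_out in zip(sizes[:-1], sizes[1:]):
            scale = np.sqrt(2.0 / fan_in)
            self.W.append(rng.standard_normal((fan_in, fan_out)) * scale)
            self.b.append(np.zeros(fan_out))
        self.mu = np.zeros(sizes[0])
        self.sd = np.ones(sizes[0])

    def set_standardizer(self, X: np.ndarray) -> None:
        self.mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self.sd = np.where(sd > 1e-12, sd, 1.0)

    def forward(self, X: np.ndarray, dropout: float = 0.0,
                rng: np.random.Generator | None = None):
        h = (np.asarray(X, dtype=float) - self.mu) / self.sd
        cache = [h]
        masks = []
        n_layers = len(self.W)
        for i, (W, b) in enumerate(zip(self.W, self.b)):
            z = h @ W + b
            if i < n_layers - 1:
                h = np.maximum(z, 0.0)
                if dropout > 0.0 and rng is not None:
                    mask = (rng.random(h.shape) >= dropout) / (1.0 - dropout)
                    h = h * mask
                    masks.append(mask)
                else:
                    masks.append(None)
                cache.append(h)
            else:
                h = z[:, 0]
        if rng is None and dropout == 0.0:
            return h
        self._cache, self._masks = cache, masks
        return h

    def backward(self, pred: np.ndarray, y: np.ndarray, l2: float):
        n = len(y)
        grads_W = [None] * len(self.W)
        grads_b = [None] * len(self.b)
        delta = (2.0 / n) * (pred - y)            # d loss / d output
        delta = delta[:, None]
        for i in range(len(self.W) - 1, -1, -1):
            h_in = self._cache[i]
            grads_W[i] = h_in.T @ delta + 2.0 * l2 * self.W[i]
            grads_b[i] = delta.sum(axis=0)
            if i > 0:
                delta = delta @ self.W[i].T
                mask = self._masks[i - 1]
                if mask is not None:
                    delta = delta * mask
                delta = delta * (self._cache[i] > 0.0)
        return grads_W, grads_b

    def step(self, grads_W, grads_b, lr: float) -> None:
        for i in range(len(self.W)):
            self.W[i] -= lr * grads_W[i]
            self.b[i] -= lr * grads_b[i]

    def snapshot(self):
        return ([W.copy() for W in self.W], [b.copy() for b in self.b])

    def restore(self, snap) -> None:
        self.W = [W.copy() for W in snap[0]]
        self.b = [b.copy() for b in snap[1]]


def _safe_pearson(pred: np.ndarray, gold: np.ndarray) -> float:
    if np.std(pred) < 1e-12 or np.std(gold) < 1e-12:
        return -np.inf
    return float(np.corrcoef(pred, gold)[0, 1])


def train_encoder(
    train_pairs: Sequence[SentencePair],
    val_pairs: Sequence[SentencePair],
    backend: EmbeddingBackend,
    cfg: EncoderConfig = EncoderConfig(),
    fingerprint: str | None = None,
) -> ModelBundle:
    """Train the encoder network on sentence-pair embeddings.

    Early stopping monitors validation MSE with ``cfg.patience_epochs``
    patience; the returned bundle holds the epoch checkpoint with the
    highest validation Pearson correlation.  Training is bit-reproducible
    for a fixed seed, data and backend.
    """
    if not val_pairs:
        raise InvalidInputError("validation set must be non-empty")
    y_tr = _check_scores([p.gold_score for p in train_pairs])
    y_va = _check_scores([p.gold_score for p in val_pairs])
    X_tr = encoder_inputs(train_pairs, backend, cfg.elementwise_product)
    X_va = encoder_inputs(val_pairs, backend, cfg.elementwise_product)

    rng = np.random.default_rng(cfg.seed)
    net = _EncoderNet([X_tr.shape[1], *cfg.hidden_sizes, 1], rng)
    net.set_standardizer(X_tr)
    net.b[-1][:] = y_tr.mean()

    best_val_mse = np.inf
    best_pearson = -np.inf
    best_snap = net.snapshot()
    best_epoch = 0
    stall = 0
    n = len(train_pairs)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            pred = net.forward(X_tr[idx], dropout=cfg.dropout, rng=rng)
            if not np.all(np.isfinite(pred)):
                raise TrainingError(f"non-finite activations at epoch {epoch}")
            gW, gb = net.backward(pred, y_tr[idx], cfg.l2_lambda)
            net.step(gW, gb, cfg.learning_rate)
        val_pred = net.forward(X_va)
        val_mse = float(np.mean((val_pred - y_va) ** 2))
        if not np.isfinite(val_mse):
            raise TrainingError(f"non-finite validation loss at epoch {epoch}")
        r = _safe_pearson(val_pred, y_va)
        if r > best_pearson:
            best_pearson = r
            best_snap = net.snapshot()
            best_epoch = epoch
        if val_mse < best_val_mse - 1e-9:
            best_val_mse = val_mse
            stall = 0
        else:
            stall += 1
            if stall >= cfg.patience_epochs:
                break
    net.restore(best_snap)
    return ModelBundle(
        kind="encoder",
        predictor=net,
        fingerprint=fingerprint,
        seed=cfg.seed,
        meta={
            "config": cfg,
            "best_val_pearson": best_pearson,
            "best_val_mse": best_val_mse,
            "best_epoch": best_epoch,
            "input_dim": X_tr.shape[1],
        },
    )


# ---------------------------------------------------------------------------
# Stacking ensemble
# ---------------------------------------------------------------------------

def train_ensemble(
    component_predictions: np.ndarray,
    validation_scores: Sequence[float],
    fingerprint: str | None = None,
) -> ModelBundle:
    """Ordinary-least-squares stacking over component model predictions.

    ``component_predictions`` has one column per component model, evaluated
    on the validation split; duplicate identical columns are dropped (with a
    log message) before the fit to avoid a rank-deficient design.
    """
    P = np.asarray(component_predictions, dtype=float)
    if P.ndim == 1:
        P = P[:, None]
    if P.shape[1] == 0:
        raise InvalidInputError("ensemble needs at least one component column")
    y = _check_scores(validation_scores)
    if P.shape[0] != y.shape[0]:
        raise InvalidInputError("row count must match validation size")
    keep: list[int] = []
    for j in range(P.shape[1]):
        if any(np.array_equal(P[:, j], P[:, k]) for k in keep):
            logger.info("dropping duplicate ensemble component column %d", j)
            continue
        keep.append(j)
    design = np.column_stack([P[:, keep], np.ones(P.shape[0])])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    w, b = coef[:-1], float(coef[-1])
    return ModelBundle(
        kind="ensemble",
        predictor=(w, b, keep),
        fingerprint=fingerprint,
        meta={"weights": w.tolist(), "intercept": b,
              "kept_columns": keep, "n_components_original": P.shape[1]},
    )


def predict(bundle: ModelBundle, X: np.ndarray, fingerprint: str | None = None) -> np.ndarray:
    """Module-level alias of :meth:`ModelBundle.predict`."""
    return bundle.predict(X, fingerprint=fingerprint)


# ---------------------------------------------------------------------------
# Bundle serialization: one directory with a params file + JSON config
# ---------------------------------------------------------------------------

def save_bundle(bundle: ModelBundle, directory) -> None:
    """Serialize a fitted bundle into *directory* (params + bundle.json)."""
    from pathlib import Path

    import joblib

    path = Path(directory)
    path.mkdir(parents=True, exist_ok=True)
    meta = dict(bundle.meta)
    cfg = meta.pop("config", None)
    info = {
        "kind": bundle.kind,
        "fingerprint": bundle.fingerprint,
        "seed": bundle.seed,
        "meta": meta,
    }
    if bundle.kind == "random_forest":
        joblib.dump(bundle.predictor, path / "params.joblib")
    elif bundle.kind == "encoder":
        from dataclasses import asdict

        info["encoder_config"] = asdict(cfg)
        net = bundle.predictor
        arrays = {f"W{i}": W for i, W in enumerate(net.W)}
        arrays |= {f"b{i}": b for i, b in enumerate(net.b)}
        arrays |= {"mu": net.mu, "sd": net.sd}
        np.savez(path / "params.npz", **arrays)
    elif bundle.kind == "ensemble":
        w, b, keep = bundle.predictor
        info["params"] = {"weights": list(w), "intercept": b, "keep": keep}
    else:  # pragma: no cover
        raise InvalidInputError(f"cannot serialize bundle kind {bundle.kind!r}")
    (path / "bundle.json").write_text(json.dumps(info, indent=2), "utf-8")


def load_bundle(directory) -> ModelBundle:
    """Load a bundle previously written by :func:`save_bundle`."""
    from pathlib import Path

    import joblib

    path = Path(directory)
    info = json.loads((path / "bundle.json").read_text("utf-8"))
    kind = info["kind"]
    meta = info.get("meta", {})
    if kind == "random_forest":
        predictor = joblib.load(path / "params.joblib")
    elif kind == "encoder":
        cfg_d = info["encoder_config"]
        cfg = EncoderConfig(**{**cfg_d, "hidden_sizes": tuple(cfg_d["hidden_sizes"])})
        with np.load(path / "params.npz") as data:
            n_layers = len(cfg.hidden_sizes) + 1
            sizes = [data["W0"].shape[0], *cfg.hidden_sizes, 1]
            net = _EncoderNet(sizes, np.random.default_rng(0))
            net.W = [data[f"W{i}"] for i in range(n_layers)]
            net.b = [data[f"b{i}"] for i in range(n_layers)]
            net.mu, net.sd = data["mu"], data["sd"]
        predictor = net
        meta = {**meta, "config": cfg}
    elif kind == "ensemble":
        p = info["params"]
        predictor = (np.asarray(p["weights"]), p["intercept"], list(p["keep"]))
    else:
        raise InvalidInputError(f"unknown bundle kind {kind!r}")
    return ModelBundle(
        kind=kind,
        predictor=predictor,
        fingerprint=info.get("fingerprint"),
        seed=info.get("seed"),
        meta=meta,
    )
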