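"""End-to-end training and prediction over sentence pairs.

Glues the pieces together: fit the feature context on the training split,
train the random forest on engineered features and the encoder network on
embeddings, stack the two with least squares on the validation split, and
predict on new pairs with any of the three models.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .data_io import SentencePair
from .errors import InvalidInputError, StateError
from .models import (
    EncoderConfig,
    FeatureContext,
    ModelBundle,
    encoder_inputs,
    feature_matrix,
    train_encoder,
    train_ensemble,
    train_random_forest,
)

__all__ = ["StsPipeline"]


class StsPipeline:
    """Random forest + encoder network + stacking ensemble over sentence pairs."""

    def __init__(self, ctx: FeatureContext | None = None):
        self.ctx = ctx if ctx is not None else FeatureContext()
        self.rf: ModelBundle | None = None
        self.encoder: ModelBundle | None = None
        self.ensemble: ModelBundle | None = None

    def fit(
        self,
        train_pairs: Sequence[SentencePair],
        val_pairs: Sequence[SentencePair],
        seed: int = 0,
        encoder_cfg: EncoderConfig | None = None,
    ) -> "StsPipeline":
        """Train all three models; the ensemble is fitted on validation predictions."""
        if not train_pairs or not val_pairs:
            raise InvalidInputError("both training and validation pairs are required")
        self.ctx.fit_idf(train_pairs)
        fp = self.ctx.fingerprint()
        y_train = [p.gold_score for p in train_pairs]
        y_val = np.array([p.gold_score for p in val_pairs], dtype=float)

        X_train = feature_matrix(train_pairs, self.ctx)
        self.rf = train_random_forest(X_train, y_train, seed=seed, fingerprint=fp)

        cfg = encoder_cfg if encoder_cfg is not None else EncoderConfig(seed=seed)
        self.encoder = train_encoder(
            train_pairs, val_pairs, self.ctx.backend, cfg, fingerprint=fp
        )

        P_val = np.column_stack(
            [self._predict_single(self.rf, val_pairs),
             self._predict_single(self.encoder, val_pairs)]
        )
        self.ensemble = train_ensemble(P_val, y_val, fingerprint=fp)
        return self

    def _predict_single(self, bundle: ModelBundle, pairs) -> np.ndarray:
        fp = self.ctx.fingerprint()
        if bundle.kind == "random_forest":
            return bundle.predict(feature_matrix(pairs, self.ctx), fingerprint=fp)
        if bundle.kind == "encoder":
            cfg = bundle.meta["config"]
            X = encoder_inputs(pairs, self.ctx.backend, cfg.elementwise_product)
            return bundle.predict(X, fingerprint=fp)
        raise InvalidInputError(f"cannot predict pairs with bundle kind {bundle.kind}")

    def predict(self, pairs: Sequence[SentencePair], model: str = "ensemble") -> np.ndarray:
        """Predict similarity scores in [0, 5] with the chosen model."""
        if not pairs:
            return np.zeros(0)
        if model == "random_forest":
            bundle = self._require(self.rf, model)
            return self._predict_single(bundle, pairs)
        if model == "encoder":
            bundle = self._require(self.encoder, model)
            return self._predict_single(bundle, pairs)
        if model == "ensemble":
            bundle = self._require(self.ensemble, model)
            P = np.column_stack(
                [self._predict_single(self._require(self.rf, "random_forest"), pairs),
                 self._predict_single(self._require(self.encoder, "encoder"), pairs)]
            )
            return bundle.predict(P, fingerprint=self.ctx.fingerprint())
        raise InvalidInputError(f"unknown model {model!r}")

    @staticmethod
    def _require(bundle: ModelBundle | None, name: str) -> ModelBundle:
        if bundle is None:
            raise StateError(f"{name} model is not fitted; call fit() first")
        return bundle
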