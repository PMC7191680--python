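"""Evaluation: Pearson scoring, region-wise error, ablation, feature screening.

Pearson correlation between predicted and gold scores is the headline
metric.  Error analysis decomposes mean squared error by gold-similarity
region (five unit-width bins on [0, 5] by default), feature ablation
retrains the random forest with one feature family removed at a time, and
single-feature screening reports each raw feature's unsupervised correlation
with the gold scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import InvalidInputError, UndefinedCorrelationError
from .models import FEATURE_FAMILIES, FEATURE_NAMES, train_random_forest

__all__ = [
    "pearson",
    "region_mse",
    "EvalReport",
    "evaluate",
    "DatasetSplits",
    "ablate",
    "single_feature_correlations",
    "feature_importance_table",
    "DEFAULT_REGION_BINS",
]

#: Unit-width gold-score bins; the first is closed on both ends.
DEFAULT_REGION_BINS: tuple[tuple[float, float], ...] = (
    (0.0, 1.0), (1.0, 2.0), (2.0, 3.0), (3.0, 4.0), (4.0, 5.0),
)


def pearson(pred: Sequence[float], gold: Sequence[float]) -> float:
    """Sample Pearson correlation; constant inputs raise rather than return 0."""
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape or p.ndim != 1 or p.size < 2:
        raise InvalidInputError("pearson needs two equal-length vectors of size >= 2")
    if np.ptp(p) == 0.0 or np.ptp(g) == 0.0:
        raise UndefinedCorrelationError("correlation undefined for a constant vector")
    return float(stats.pearsonr(p, g).statistic)


def _bin_label(lo: float, hi: float, first: bool) -> str:
    return f"[{lo:g},{hi:g}]" if first else f"({lo:g},{hi:g}]"


def region_mse(
    pred: Sequence[float],
    gold: Sequence[float],
    bins: Sequence[tuple[float, float]] = DEFAULT_REGION_BINS,
) -> dict[str, dict[str, float]]:
    """Mean squared error per gold-similarity region.

    Pairs are assigned to the bin containing their *gold* score (bins are
    half-open ``(lo, hi]`` except the first, which includes its lower edge).
    Empty bins are absent from the result rather than reported as zero.
    """
    p = np.asarray(pred, dtype=float)
    g = np.asarray(gold, dtype=float)
    if p.shape != g.shape:
        raise InvalidInputError("pred and gold must have equal length")
    out: dict[str, dict[str, float]] = {}
    for k, (lo, hi) in enumerate(bins):
        mask = (g > lo) & (g <= hi)
        if k == 0:
            mask |= g == lo
        if not mask.any():
            continue
        err = p[mask] - g[mask]
        out[_bin_label(lo, hi, k == 0)] = {
            "mse": float(np.mean(err**2)),
            "n": int(mask.sum()),
        }
    return out


@dataclass
class EvalReport:
    """Pearson correlation plus the region-wise error table for one model."""

    pearson: float
    n_pairs: int
    region_mse: dict[str, dict[str, float]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "pearson": self.pearson,
            "n_pairs": self.n_pairs,
            "region_mse": self.region_mse,
        }


def evaluate(
    pred: Sequence[float],
    gold: Sequence[float],
    bins: Sequence[tuple[float, float]] = DEFAULT_REGION_BINS,
) -> EvalReport:
    """Score predictions against gold: Pearson plus region-wise MSE."""
    return EvalReport(
        pearson=pearson(pred, gold),
        n_pairs=len(list(gold)),
        region_mse=region_mse(pred, gold, bins),
    )


@dataclass
class DatasetSplits:
    """Feature matrices and gold scores of the train/validation/test splits."""

    X_train: np.ndarray
    y_train: np.ndarray
    X_val: np.ndarray
    y_val: np.ndarray
    X_test: np.ndarray
    y_test: np.ndarray


def _fit_and_score(X_tr, y_tr, X_va, y_va, X_te, y_te, cols, seed):
    bundle = train_random_forest(X_tr[:, cols], y_tr, seed=seed)
    r_val = pearson(bundle.predict(X_va[:, cols]), y_va)
    r_test = pearson(bundle.predict(X_te[:, cols]), y_te)
    return r_val, r_test


def ablate(
    splits: DatasetSplits,
    families: Sequence[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Feature-family ablation of the random forest.

    For each named family the forest is retrained (same seed) without that
    family's feature slots; the table reports validation and test Pearson
    and the deltas against the full 14-feature model, which appears as the
    first row.
    """
    if families is None:
        families = list(FEATURE_FAMILIES)
    unknown = set(families) - set(FEATURE_FAMILIES)
    if unknown:
        raise InvalidInputError(f"unknown feature families: {sorted(unknown)}")
    all_cols = list(range(len(FEATURE_NAMES)))
    r_val_full, r_test_full = _fit_and_score(
        splits.X_train, splits.y_train, splits.X_val, splits.y_val,
        splits.X_test, splits.y_test, all_cols, seed,
    )
    rows = [{
        "family": "full",
        "n_features_removed": 0,
        "validation_pearson": r_val_full,
        "test_pearson": r_test_full,
        "delta_validation": 0.0,
        "delta_test": 0.0,
    }]
    for fam in families:
        dropped = set(FEATURE_FAMILIES[fam])
        cols = [i for i, n in enumerate(FEATURE_NAMES) if n not in dropped]
        r_val, r_test = _fit_and_score(
            splits.X_train, splits.y_train, splits.X_val, splits.y_val,
            splits.X_test, splits.y_test, cols, seed,
        )
        rows.append({
            "family": fam,
            "n_features_removed": len(dropped),
            "validation_pearson": r_val,
            "test_pearson": r_test,
            "delta_validation": r_val - r_val_full,
            "delta_test": r_test - r_test_full,
        })
    return pd.DataFrame(rows)


def single_feature_correlations(
    X: np.ndarray,
    gold: Sequence[float],
    include_entity: bool = False,
) -> dict[str, float | None]:
    """Unsupervised Pearson of each raw feature column against the gold scores.

    Entity-based features are excluded by default since they only apply to
    concept-bearing sentences; a constant feature column is reported as
    ``None`` (undefined correlation) rather than silently dropped.
    """
    X = np.asarray(X, dtype=float)
    excluded = set() if include_entity else set(FEATURE_FAMILIES["entity"])
    out: dict[str, float | None] = {}
    for i, name in enumerate(FEATURE_NAMES):
        if name in excluded:
            continue
        try:
            out[name] = pearson(X[:, i], gold)
        except UndefinedCorrelationError:
            out[name] = None
    return out


def feature_importance_table(forest_bundle) -> pd.DataFrame:
    """Random-forest impurity importances as a ranked table."""
    imp = forest_bundle.predictor.feature_importances_
    df = pd.DataFrame({"feature": FEATURE_NAMES[: len(imp)], "importance": imp})
    return df.sort_values("importance", ascending=False).reset_index(drop=True)
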