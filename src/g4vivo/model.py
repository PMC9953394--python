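"""Gradient-boosted tree classifier for in vivo G4 activity, and the
one-cell-line / cross-cell-line evaluation drivers.

The estimator is LightGBM with native categorical-feature support: the
ordinal sequence columns are declared categorical so each split sorts the
base categories by training objective instead of imposing the arbitrary
A<T<C<G order. Training is single-threaded and deterministic by default so a
(data, hyperparameters, seed) triple is bit-reproducible.

Modelling surface follows the model/results idiom: build a
:class:`G4ActivityModel` from a labeled dataset, call :meth:`fit` to get a
:class:`G4ActivityResults` that scores, evaluates, summarises and persists.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field
from typing import Callable

import lightgbm as lgb
import numpy as np

from .dataset import (
    LabeledDataset,
    SplitSpec,
    oversample_positives,
    stratified_half_split,
)
from .features import FeatureConfig, FeatureMatrix
from .metrics import (
    MetricsReport,
    RepeatedReport,
    aggregate_reports,
    compute_metrics,
    threshold_calls,
)

log = logging.getLogger(__name__)

__all__ = [
    "HyperParams",
    "G4ActivityModel",
    "G4ActivityResults",
    "train_gbdt",
    "predict_scores",
    "threshold_calls",
    "repeated_evaluation",
    "one_cell_line_experiment",
    "cross_cell_line_experiment",
]


@dataclass(frozen=True)
class HyperParams:
    """GBDT hyperparameters (binary log-loss objective is fixed).

    Defaults are moderate library defaults for a few-thousand-row balanced
    training set, plus per-tree column subsampling (``feature_fraction``).
    Subsampling matters here: an oversampled training set can hold few
    *distinct* positive rows, so many accessibility windows separate the
    training classes perfectly and greedy trees are free to pick
    razor-margin thresholds that do not generalize; forcing each tree to see
    half the columns makes the ensemble average over many windows instead.
    ``extra`` passes any further backend parameter through untouched.
    """

    n_estimators: int = 500
    learning_rate: float = 0.1
    num_leaves: int = 31
    min_child_samples: int = 20
    feature_fraction: float = 0.5
    n_jobs: int = 1
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        if not 0 < self.feature_fraction <= 1:
            raise ValueError("feature_fraction must be in (0, 1]")

    def lgb_params(self, seed: int) -> dict:
        params = {
            "objective": "binary",
            "n_estimators": self.n_estimators,
            "learning_rate": self.learning_rate,
            "num_leaves": self.num_leaves,
            "min_child_samples": self.min_child_samples,
            "colsample_bytree": self.feature_fraction,
            "random_state": seed,
            "n_jobs": self.n_jobs,
            "verbose": -1,
        }
        if self.n_jobs == 1:
            params["deterministic"] = True
            params["force_row_wise"] = True
        else:
            log.warning(
                "n_jobs=%d: parallel training relinquishes bit-reproducibility",
                self.n_jobs,
            )
        params.update(self.extra)
        return params


class G4ActivityModel:
    """Unfitted model: a labeled training dataset plus hyperparameters."""

    def __init__(self, train: LabeledDataset, hyperparams: HyperParams | None = None):
        if train.n_positive == 0 or train.n_negative == 0:
            raise ValueError("training data must contain both classes")
        self.train_data = train
        self.hyperparams = hyperparams or HyperParams()

    def fit(self, seed: int = 0) -> "G4ActivityResults":
        fm = self.train_data.features
        params = self.hyperparams.lgb_params(seed)
        clf = lgb.LGBMClassifier(**params)
        names = fm.column_names()
        clf.fit(
            fm.data,
            np.asarray(self.train_data.labels, int),
            feature_name=names if len(names) == fm.n_columns else "auto",
            categorical_feature=fm.categorical_indices,
        )
        provenance = {
            "seed": seed,
            "hyperparams": {**vars(self.hyperparams)},
            "n_train": len(self.train_data),
            "n_positive": self.train_data.n_positive,
            "schema_digest": fm.schema_digest(),
        }
        log.info("trained GBDT: %s", provenance)
        return G4ActivityResults(clf.booster_, _schema_of(fm), provenance)


def _schema_of(fm: FeatureMatrix) -> dict:
    return {
        "n_columns": fm.n_columns,
        "categorical": fm.categorical_indices,
        "mode": fm.mode,
        "flank": fm.config.flank,
        "window": fm.config.window,
        "strand_orient": fm.config.strand_orient,
        "unknown_code": fm.config.unknown_code,
        "digest": fm.schema_digest(),
    }


class G4ActivityResults:
    """Fitted ensemble plus the feature schema it was trained on.

    Prediction refuses feature matrices whose schema digest differs from
    training — a strand-orientation or feature-mode mismatch silently
    scrambles categorical codes otherwise.
    """

    def __init__(self, booster: lgb.Booster, schema: dict, provenance: dict):
        self.booster = booster
        self.schema = schema
        self.provenance = provenance

    def predict_scores(self, features: FeatureMatrix) -> np.ndarray:
        """One activity probability in [0, 1] per row."""
        if features.schema_digest() != self.schema["digest"]:
            raise ValueError(
                "feature schema mismatch: model was trained on "
                f"{self.schema['mode']!r} features "
                f"({self.schema['n_columns']} columns, digest "
                f"{self.schema['digest']}), got {features.mode!r} "
                f"({features.n_columns} columns, digest {features.schema_digest()})"
            )
        if features.n_rows == 0:
            return np.zeros(0)
        return np.asarray(self.booster.predict(features.data), dtype=float)

    def evaluate(self, ds: LabeledDataset, threshold: float = 0.5) -> MetricsReport:
        return compute_metrics(ds.labels, self.predict_scores(ds.features), threshold)

    def summary(self) -> str:
        hp = self.provenance.get("hyperparams", {})
        lines = [
            "G4 activity model (gradient-boosted trees)",
            f"  features: {self.schema['mode']} "
            f"({self.schema['n_columns']} columns, "
            f"{len(self.schema['categorical'])} categorical)",
            f"  flank={self.schema['flank']} window={self.schema['window']} "
            f"strand_orient={self.schema['strand_orient']}",
            f"  trained on {self.provenance.get('n_train', '?')} rows "
            f"({self.provenance.get('n_positive', '?')} positive), "
            f"seed {self.provenance.get('seed', '?')}",
            "  hyperparameters: "
            + ", ".join(f"{k}={v}" for k, v in hp.items() if k != "extra"),
        ]
        imp = self.booster.feature_importance(importance_type="gain")
        top = np.argsort(imp)[::-1][:5]
        names = self.booster.feature_name()
        lines.append(
            "  top features by gain: "
            + ", ".join(f"{names[i]} ({imp[i]:.0f})" for i in top if imp[i] > 0)
        )
        return "\n".join(lines)

    def save(self, path: str | os.PathLike) -> None:
        """Persist as a single JSON file (model text + schema + provenance)."""
        payload = {
            "schema": self.schema,
            "provenance": self.provenance,
            "model": self.booster.model_to_string(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path: str | os.PathLike) -> "G4ActivityResults":
        with open(path) as fh:
            payload = json.load(fh)
        booster = lgb.Booster(model_str=payload["model"])
        return cls(booster, payload["schema"], payload["provenance"])


# ---------------------------------------------------------------------------
# Functional wrappers and experiment drivers


def train_gbdt(
    train: LabeledDataset, hp: HyperParams | None = None, seed: int = 0
) -> G4ActivityResults:
    """Fit the classifier on an (already balanced, if desired) training set."""
    return G4ActivityModel(train, hp).fit(seed)


def predict_scores(model: G4ActivityResults, features: FeatureMatrix) -> np.ndarray:
    return model.predict_scores(features)


def one_cell_line_experiment(
    ds: LabeledDataset,
    hp: HyperParams | None = None,
    mode: str = "both",
    seed: int = 0,
    threshold: float = 0.5,
    train_fraction: float = 0.5,
) -> MetricsReport:
    """Within-cell-line protocol: stratified half-split, oversample the
    training half, train, score the untouched test half at ``threshold``.

    ``mode`` restricts the feature block (atac / seq / both) for ablations.
    The input dataset is left unmodified.
    """
    sub = ds.with_mode(mode)
    train, test = stratified_half_split(sub, SplitSpec(train_fraction, seed))
    balanced = oversample_positives(train, seed)
    results = train_gbdt(balanced, hp, seed)
    return results.evaluate(test, threshold)


def cross_cell_line_experiment(
    train_ds: LabeledDataset,
    test_ds: LabeledDataset,
    hp: HyperParams | None = None,
    mode: str = "both",
    seed: int = 0,
    threshold: float = 0.5,
) -> MetricsReport:
    """Transfer protocol: oversample ALL of one cell line's data (no split),
    train, evaluate on the full second cell line."""
    train_sub = train_ds.with_mode(mode)
    test_sub = test_ds.with_mode(mode)
    if train_sub.features.schema_digest() != test_sub.features.schema_digest():
        raise ValueError("train and test feature schemas differ")
    balanced = oversample_positives(train_sub, seed)
    results = train_gbdt(balanced, hp, seed)
    return results.evaluate(test_sub, threshold)


def repeated_evaluation(
    protocol: Callable[[int], MetricsReport], base_seed: int = 0, k: int = 5
) -> RepeatedReport:
    """Run ``protocol(seed)`` for seeds ``base_seed .. base_seed + k - 1`` and
    aggregate each metric as mean +/- standard error."""
    if k < 2:
        raise ValueError("repeated evaluation requires k >= 2")
    return aggregate_reports([protocol(base_seed + i) for i in range(k)])
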