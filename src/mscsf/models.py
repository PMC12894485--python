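"""Probability-producing classifiers and the severity regressor.

Random forests consume the panel log-ratio features: one forest separates
MS from non-MS, one separates relapsing-remitting from progressive MS, and
a regression forest predicts the composite severity score (MS-DSS) that
feeds the prognostic chain. Probabilities are vote fractions over the
forest (each fully grown tree casts one class vote) and are dichotomized
at a fixed cutoff, 0.5 by default, with ties assigned to the negative
class. Feature columns are matched by name and order at prediction time;
a mismatch is an error, never silently reindexed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from mscsf.roc import _auc_core

__all__ = [
    "DiagnosticModel",
    "train_classifier",
    "train_severity_regressor",
    "predict_probabilities",
    "classify",
]

MODEL_KINDS = ("ms_vs_nonms", "rrms_vs_progms", "severity_regression")


@dataclass
class DiagnosticModel:
    """A fitted forest plus the metadata needed to apply it safely."""

    model_kind: str
    panel_name: str
    estimator: object
    feature_names: tuple[str, ...]
    n_trees: int
    seed: Optional[int]
    n_samples: int
    class_balance: Optional[dict] = None
    oob_auc: Optional[float] = None
    cutoff: float = 0.5
    probability_mode: str = "vote"  # "vote" or "leaf"
    training_provenance: str = "unknown"

    def __post_init__(self):
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model_kind {self.model_kind!r}")
        if not 0.0 < self.cutoff < 1.0:
            raise ValueError("cutoff must be in (0, 1)")
        if self.n_trees < 100:
            raise ValueError("forest needs at least 100 trees")

    def save(self, outdir) -> None:
        """Persist config + metadata as JSON and the fitted forest as a
        joblib bundle alongside it."""
        import joblib

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        meta = {k: v for k, v in self.__dict__.items() if k != "estimator"}
        meta["feature_names"] = list(self.feature_names)
        (outdir / "model.json").write_text(json.dumps(meta, indent=2, default=str))
        joblib.dump(self.estimator, outdir / "forest.joblib")

    @classmethod
    def load(cls, indir) -> "DiagnosticModel":
        import joblib

        indir = Path(indir)
        meta = json.loads((indir / "model.json").read_text())
        meta["feature_names"] = tuple(meta["feature_names"])
        est = joblib.load(indir / "forest.joblib")
        return cls(estimator=est, **meta)


def _check_features(features: pd.DataFrame):
    if features.isna().any().any():
        raise ValueError("feature matrix contains missing values; no imputation is done")


def train_classifier(
    features: pd.DataFrame,
    labels,
    model_kind: str = "ms_vs_nonms",
    n_trees: int = 500,
    max_features: str | float = "sqrt",
    seed: Optional[int] = None,
    cutoff: float = 0.5,
    probability_mode: str = "vote",
    stratify_bootstrap: bool = False,
    training_provenance: str = "unknown",
) -> DiagnosticModel:
    """Fit a probability-producing random-forest classifier.

    Trees are fully grown with ``max_features`` candidates per split. The
    out-of-bag vote fractions give an internal AUROC estimate stored in
    metadata. Deterministic for a fixed seed.
    """
    labels = np.asarray(labels)
    y = labels.astype(bool) if labels.dtype == bool else np.asarray(labels, float) > 0.5
    if len(y) != len(features):
        raise ValueError("features and labels length mismatch")
    if y.all() or not y.any():
        raise ValueError("training labels contain a single class")
    if min(y.sum(), (~y).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    _check_features(features)

    est = RandomForestClassifier(
        n_estimators=n_trees,
        max_features=max_features,
        oob_score=True,
        random_state=seed,
        class_weight="balanced_subsample" if stratify_bootstrap else None,
        n_jobs=1,
    )
    est.fit(features.to_numpy(float), y.astype(int))
    oob = est.oob_decision_function_[:, 1]
    valid = ~np.isnan(oob)
    oob_auc = None
    if valid.sum() > 2 and 0 < y[valid].sum() < valid.sum():
        oob_auc = _auc_core(oob[valid], y[valid])

    return DiagnosticModel(
        model_kind=model_kind,
        panel_name=features.attrs.get("panel_name", "unknown"),
        estimator=est,
        feature_names=tuple(features.columns),
        n_trees=n_trees,
        seed=seed,
        n_samples=len(features),
        class_balance={"positive": int(y.sum()), "negative": int((~y).sum())},
        oob_auc=oob_auc,
        cutoff=cutoff,
        probability_mode=probability_mode,
        training_provenance=training_provenance,
    )


def train_severity_regressor(
    features: pd.DataFrame,
    targets,
    n_trees: int = 500,
    max_features: str | float = 1.0 / 3.0,
    seed: Optional[int] = None,
    min_samples: int = 30,
    training_provenance: str = "unknown",
) -> DiagnosticModel:
    """Fit the regression forest that predicts the severity score (MS-DSS)
    from severity-panel ratios."""
    targets = np.asarray(targets, dtype=float)
    if len(targets) != len(features):
        raise ValueError("features and targets length mismatch")
    if len(features) < min_samples:
        raise ValueError(f"severity regression needs >= {min_samples} samples")
    if np.ptp(targets) == 0:
        raise ValueError("constant severity target: nothing to regress")
    _check_features(features)
    est = RandomForestRegressor(
        n_estimators=n_trees, max_features=max_features, random_state=seed, n_jobs=1
    )
    est.fit(features.to_numpy(float), targets)
    return DiagnosticModel(
        model_kind="severity_regression",
        panel_name=features.attrs.get("panel_name", "unknown"),
        estimator=est,
        feature_names=tuple(features.columns),
        n_trees=n_trees,
        seed=seed,
        n_samples=len(features),
        training_provenance=training_provenance,
    )


def _match_columns(model: DiagnosticModel, features: pd.DataFrame):
    got = tuple(features.columns)
    if got != model.feature_names:
        missing = [c for c in model.feature_names if c not in got]
        extra = [c for c in got if c not in model.feature_names]
        raise ValueError(
            "feature columns do not match training columns "
            f"(missing={missing}, unexpected={extra}, order must match exactly)"
        )


def predict_probabilities(model: DiagnosticModel, features: pd.DataFrame) -> pd.Series:
    """Per-row probability (classifier) or severity prediction (regressor).

    Classifier probabilities are vote fractions: the share of trees whose
    predicted class is positive. ``probability_mode='leaf'`` averages the
    per-tree leaf class frequencies instead (identical for fully grown
    trees with pure leaves).
    """
    _match_columns(model, features)
    if len(features) == 0:
        return pd.Series(dtype=float, index=features.index)
    _check_features(features)
    X = features.to_numpy(float)
    est = model.estimator
    if model.model_kind == "severity_regression":
        return pd.Series(est.predict(X), index=features.index)
    if model.probability_mode == "vote":
        votes = np.zeros(len(X))
        for tree in est.estimators_:
            votes += tree.predict_proba(X).argmax(axis=1)
        prob = votes / len(est.estimators_)
    else:
        prob = est.predict_proba(X)[:, 1]
    return pd.Series(prob, index=features.index)


def classify(probability: float, cutoff: float = 0.5) -> bool:
    """Dichotomize a probability at the cutoff.

    Positive iff probability > cutoff; equality goes to the negative class
    (the conservative tie rule for sensitivity claims).
    """
    if probability is None or (isinstance(probability, float) and np.isnan(probability)):
        raise ValueError("probability is missing")
    if not 0.0 <= probability <= 1.0:
        raise ValueError(f"probability {probability!r} outside [0, 1]")
    return bool(probability > cutoff)
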