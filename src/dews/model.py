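"""L2-regularized logistic risk model with grouped, stratified CV.

The regularization strength is chosen to maximise mean cross-validated
AUROC over a grid; folds are grouped by admission episode (no episode ever
contributes rows to two folds) and stratified on the episode-level outcome
(any positive row). The final model is refit on all training rows at the
chosen strength; features are normalised to zero mean and unit variance
with constants estimated on the training rows only.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from . import evaluation
from .features import FEATURE_NAMES, MANIFEST_VERSION, Normalizer

logger = logging.getLogger(__name__)

#: Inverse regularization strengths (sklearn's C), log-spaced.
DEFAULT_REG_GRID = tuple(np.logspace(-3, 3, 7))

OPTIMIZER_TOL = 1e-8
OPTIMIZER_MAX_ITER = 1000


class TrainingError(ValueError):
    """Training cannot proceed (degenerate labels, non-convergence, ...)."""


@dataclass
class TrainedModel:
    feature_names: tuple[str, ...]
    coefficients: dict[str, float]
    intercept: float
    reg_strength: float  # sklearn C (inverse strength)
    normalizer: Normalizer
    outcome: str
    manifest_version: str = MANIFEST_VERSION
    cv_auroc: list[float] = field(default_factory=list)
    seed: Optional[int] = None
    reg_grid: tuple[float, ...] = DEFAULT_REG_GRID

    def __post_init__(self) -> None:
        if tuple(self.coefficients) != tuple(self.feature_names):
            raise ValueError("coefficient names do not match the manifest")

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        """Probability of the outcome for each row of raw features."""
        missing = [n for n in self.feature_names if n not in features.columns]
        if missing:
            raise ValueError(f"feature columns missing: {', '.join(missing)}")
        x = features[list(self.feature_names)].to_numpy(dtype=float)
        z = self.normalizer.transform(x)
        w = np.array([self.coefficients[n] for n in self.feature_names])
        eta = self.intercept + z @ w
        return 1.0 / (1.0 + np.exp(-eta))

    def to_json(self, path: str | Path) -> None:
        doc = {
            "feature_names": list(self.feature_names),
            "coefficients": self.coefficients,
            "intercept": self.intercept,
            "reg_strength": self.reg_strength,
            "normalizer": self.normalizer.to_dict(),
            "outcome": self.outcome,
            "manifest_version": self.manifest_version,
            "cv_auroc": self.cv_auroc,
            "seed": self.seed,
            "reg_grid": list(self.reg_grid),
        }
        Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "TrainedModel":
        doc = json.loads(Path(path).read_text())
        names = tuple(doc["feature_names"])
        return cls(
            feature_names=names,
            # JSON serialisation sorts keys; restore manifest order
            coefficients={n: doc["coefficients"][n] for n in names},
            intercept=doc["intercept"],
            reg_strength=doc["reg_strength"],
            normalizer=Normalizer.from_dict(doc["normalizer"]),
            outcome=doc["outcome"],
            manifest_version=doc.get("manifest_version", MANIFEST_VERSION),
            cv_auroc=doc.get("cv_auroc", []),
            seed=doc.get("seed"),
            reg_grid=tuple(doc.get("reg_grid", DEFAULT_REG_GRID)),
        )


def episode_folds(
    episode_ids: Sequence[str],
    labels: Sequence[int],
    folds: int,
    seed: Optional[int],
) -> list[np.ndarray]:
    """Row-index folds grouped by episode, stratified on episode outcome.

    When fewer positive episodes than folds exist the fold count is reduced
    (with a warning) so every fold can hold a positive episode.
    """
    ids = np.asarray(episode_ids)
    y = np.asarray(labels, dtype=int)
    unique_ids, inverse = np.unique(ids, return_inverse=True)
    ep_outcome = np.zeros(unique_ids.size, dtype=int)
    np.maximum.at(ep_outcome, inverse, y)
    n_pos_ep = int(ep_outcome.sum())
    if n_pos_ep == 0 or n_pos_ep == unique_ids.size:
        raise TrainingError("need both positive and negative episodes")
    if n_pos_ep < folds:
        logger.warning(
            "only %d positive episodes; reducing folds from %d to %d",
            n_pos_ep,
            folds,
            n_pos_ep,
        )
        folds = max(2, n_pos_ep)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    out = []
    for _, test_ep_idx in skf.split(unique_ids, ep_outcome):
        mask = np.isin(inverse, test_ep_idx)
        out.append(np.flatnonzero(mask))
    return out


def _fit_logistic(
    z: np.ndarray, y: np.ndarray, C: float, seed: Optional[int]
) -> LogisticRegression:
    clf = LogisticRegression(
        C=C,  # L2 penalty (sklearn default), C = inverse strength
        solver="lbfgs",
        tol=OPTIMIZER_TOL,
        max_iter=OPTIMIZER_MAX_ITER,
        random_state=seed,
    )
    clf.fit(z, y)
    if int(np.max(clf.n_iter_)) >= OPTIMIZER_MAX_ITER:
        raise TrainingError(
            f"logistic solver failed to converge at C={C:g} "
            f"within {OPTIMIZER_MAX_ITER} iterations"
        )
    return clf


def train_dews(
    table: pd.DataFrame,
    outcome: str = "d_icu",
    feature_names: Sequence[str] = FEATURE_NAMES,
    folds: int = 10,
    reg_grid: Sequence[float] = DEFAULT_REG_GRID,
    seed: Optional[int] = 0,
) -> TrainedModel:
    """Train the risk model on a labelled feature table.

    ``table`` must contain ``episode_id``, ``label`` and the feature
    columns. Deterministic given identical inputs and seed.
    """
    feature_names = tuple(feature_names)
    y = table["label"].to_numpy(dtype=int)
    if y.min() == y.max():
        raise TrainingError("training labels contain a single class")
    x = table[list(feature_names)].to_numpy(dtype=float)
    fold_indices = episode_folds(table["episode_id"], y, folds, seed)

    mean_scores = []
    for C in reg_grid:
        fold_scores = []
        try:
            for val_idx in fold_indices:
                train_mask = np.ones(len(y), dtype=bool)
                train_mask[val_idx] = False
                y_tr, y_va = y[train_mask], y[val_idx]
                if y_tr.min() == y_tr.max() or y_va.min() == y_va.max():
                    continue  # degenerate fold: no AUROC
                norm = Normalizer.fit(x[train_mask], feature_names)
                clf = _fit_logistic(norm.transform(x[train_mask]), y_tr, C, seed)
                probs = clf.predict_proba(norm.transform(x[val_idx]))[:, 1]
                fold_scores.append(evaluation.auroc(probs, y_va))
        except TrainingError as exc:
            # a non-converging grid candidate is disqualified, not fatal
            logger.warning("grid candidate C=%g disqualified: %s", C, exc)
            mean_scores.append(-np.inf)
            continue
        if not fold_scores:
            raise TrainingError("every CV fold was single-class")
        mean_scores.append(float(np.mean(fold_scores)))
    if not np.isfinite(max(mean_scores)):
        raise TrainingError("no regularization strength converged")

    best = int(np.argmax(mean_scores))
    best_C = float(reg_grid[best])
    logger.info(
        "selected C=%g (mean CV AUROC %.4f)", best_C, mean_scores[best]
    )

    # per-fold AUROC at the chosen strength, for the model card
    cv_auroc = []
    for val_idx in fold_indices:
        train_mask = np.ones(len(y), dtype=bool)
        train_mask[val_idx] = False
        y_tr, y_va = y[train_mask], y[val_idx]
        if y_tr.min() == y_tr.max() or y_va.min() == y_va.max():
            continue
        norm = Normalizer.fit(x[train_mask], feature_names)
        clf = _fit_logistic(norm.transform(x[train_mask]), y_tr, best_C, seed)
        probs = clf.predict_proba(norm.transform(x[val_idx]))[:, 1]
        cv_auroc.append(float(evaluation.auroc(probs, y_va)))

    normalizer = Normalizer.fit(x, feature_names)
    clf = _fit_logistic(normalizer.transform(x), y, best_C, seed)
    coefficients = {
        name: float(w) for name, w in zip(feature_names, clf.coef_[0])
    }
    return TrainedModel(
        feature_names=feature_names,
        coefficients=coefficients,
        intercept=float(clf.intercept_[0]),
        reg_strength=best_C,
        normalizer=normalizer,
        outcome=outcome,
        cv_auroc=cv_auroc,
        seed=seed,
        reg_grid=tuple(float(c) for c in reg_grid),
    )


def dews_score(model: TrainedModel, features: pd.DataFrame) -> np.ndarray:
    """Probability of the outcome for each feature row."""
    return model.predict_proba(features)
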