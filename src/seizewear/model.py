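"""Balanced-bootstrap boosted-tree ensemble for window classification.

Seizure windows are vastly outnumbered by baseline windows, so each of the
(default 64) ensemble branches is trained on an exactly balanced dataset:
the positives resampled with replacement to their original count, and an
equal number of negatives drawn without replacement from a rotating pool so
branches see diverse negatives.  The ensemble score is the arithmetic mean
of the branch probabilities; windows flagged as resting (no motion) are
forced to score 0, rest being treated as non-seizure by construction.

Cross-validation is patient-grouped: subjects are greedily assigned, in
descending order of seizure count, to the fold with the lightest seizure
load, so no subject straddles folds and the folds carry near-equal numbers
of seizures.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from xgboost import XGBClassifier

__all__ = [
    "BoosterConfig",
    "BranchDataset",
    "EnsembleModel",
    "balanced_bootstrap",
    "train_ensemble",
    "predict_scores",
    "assign_cv_folds",
    "cross_validate",
    "feature_importance",
    "save_model",
    "load_model",
]


@dataclass(frozen=True)
class BoosterConfig:
    """Hyperparameters shared by every branch classifier."""

    n_estimators: int = 400
    learning_rate: float = 0.1
    scale_pos_weight: float = 1.0
    subsample: float = 0.9
    reg_lambda: float = 2.0  # L2
    reg_alpha: float = 0.0  # L1
    min_child_weight: float = 3.0
    max_depth: int = 8
    n_branches: int = 64
    decision_threshold: float = 0.5

    def booster_kwargs(self) -> dict:
        return dict(
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            scale_pos_weight=self.scale_pos_weight,
            subsample=self.subsample,
            reg_lambda=self.reg_lambda,
            reg_alpha=self.reg_alpha,
            min_child_weight=self.min_child_weight,
            max_depth=self.max_depth,
            objective="binary:logistic",
            tree_method="hist",
            n_jobs=1,
            verbosity=0,
        )


@dataclass
class BranchDataset:
    """Index view of one balanced branch: equal positive and negative rows."""

    pos_idx: np.ndarray
    neg_idx: np.ndarray

    def __post_init__(self) -> None:
        if len(self.pos_idx) != len(self.neg_idx):
            raise ValueError("branch dataset must be exactly balanced")

    @property
    def indices(self) -> np.ndarray:
        return np.concatenate([self.pos_idx, self.neg_idx])

    def labels(self) -> np.ndarray:
        return np.concatenate(
            [np.ones(len(self.pos_idx), dtype=int), np.zeros(len(self.neg_idx), dtype=int)]
        )


@dataclass
class EnsembleModel:
    branches: list[XGBClassifier]
    feature_names: list[str]
    decision_threshold: float = 0.5
    training_seed: int = 0

    @property
    def n_branches(self) -> int:
        return len(self.branches)


def balanced_bootstrap(
    y: np.ndarray, n_branches: int = 64, seed: int = 0
) -> list[BranchDataset]:
    """Build ``n_branches`` exactly balanced index sets from binary labels.

    Positives are resampled with replacement to their original count per
    branch; negatives are drawn without replacement from a shuffled queue
    that is reshuffled only when exhausted, so branches use distinct
    negatives as far as supply allows.  Deterministic under ``seed``.
    """
    y = np.asarray(y).astype(int)
    pos = np.nonzero(y == 1)[0]
    neg = np.nonzero(y == 0)[0]
    if len(pos) == 0:
        raise ValueError("cannot balance-sample with zero positive rows")
    if len(neg) == 0:
        raise ValueError("cannot balance-sample with zero negative rows")
    rng = np.random.default_rng(seed)
    n_pos = len(pos)
    queue: list[int] = []
    branches = []
    for _ in range(n_branches):
        pos_b = rng.choice(pos, size=n_pos, replace=True)
        need = n_pos
        neg_b: list[int] = []
        while need > 0:
            if not queue:
                queue = list(rng.permutation(neg))
            take = min(need, len(queue))
            neg_b.extend(queue[:take])
            queue = queue[take:]
            need -= take
        branches.append(BranchDataset(pos_b, np.asarray(neg_b)))
    return branches


def train_ensemble(
    X: pd.DataFrame,
    y: np.ndarray,
    branches: Sequence[BranchDataset],
    config: BoosterConfig | None = None,
    seed: int = 0,
) -> EnsembleModel:
    """Train one independent booster per balanced branch.

    NaN feature values are passed straight through to the learner's native
    missing-value routing; no imputation happens here.
    """
    config = config or BoosterConfig()
    Xv = X.to_numpy(dtype=np.float32)
    models = []
    for i, br in enumerate(branches):
        clf = XGBClassifier(random_state=seed + i, **config.booster_kwargs())
        idx = br.indices
        clf.fit(Xv[idx], br.labels())
        models.append(clf)
    return EnsembleModel(
        models, list(X.columns), config.decision_threshold, training_seed=seed
    )


def predict_scores(
    model: EnsembleModel,
    X: pd.DataFrame,
    resting_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Mean branch probability per row, in [0, 1]; rows flagged resting are
    forced to 0 (non-motor state implies non-seizure)."""
    if list(X.columns) != model.feature_names:
        raise ValueError("feature schema mismatch between training and prediction")
    Xv = X.to_numpy(dtype=np.float32)
    scores = np.zeros(len(X))
    for clf in model.branches:
        scores += clf.predict_proba(Xv)[:, 1]
    scores /= model.n_branches
    if resting_mask is not None:
        scores = np.where(np.asarray(resting_mask, dtype=bool), 0.0, scores)
    return scores


def assign_cv_folds(
    subject_ids: Sequence[str],
    seizure_counts: Sequence[int],
    n_folds: int = 10,
    seed: int = 0,
) -> dict[str, int]:
    """Greedy seizure-balanced grouping of whole subjects into folds.

    Subjects are sorted by descending seizure count (ties broken by a seeded
    shuffle) and each is placed into the fold currently carrying the fewest
    seizures (ties: fewest subjects, then lowest index).
    """
    ids = list(subject_ids)
    counts = list(seizure_counts)
    if len(ids) < n_folds:
        raise ValueError(f"need at least {n_folds} subjects, got {len(ids)}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    order = sorted(order, key=lambda i: -counts[i])
    fold_load = np.zeros(n_folds)
    fold_size = np.zeros(n_folds, dtype=int)
    out: dict[str, int] = {}
    for i in order:
        f = min(range(n_folds), key=lambda k: (fold_load[k], fold_size[k], k))
        out[ids[i]] = f
        fold_load[f] += counts[i]
        fold_size[f] += 1
    return out


def cross_validate(
    features: pd.DataFrame,
    feature_names: Sequence[str],
    folds: dict[str, int],
    config: BoosterConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Patient-grouped cross-validation over a window-feature table.

    ``features`` must carry ``subject_id``, ``label`` and ``resting``
    columns alongside the feature columns.  For each fold an ensemble is
    trained on the positive/negative, non-resting windows of the other
    folds and scored on every held-out window; the returned copy of the
    table adds a ``score`` column (resting windows forced to 0).
    """
    config = config or BoosterConfig()
    df = features.reset_index(drop=True)
    fold_of = df["subject_id"].map(folds)
    if fold_of.isna().any():
        missing = sorted(df.loc[fold_of.isna(), "subject_id"].unique())
        raise ValueError(f"subjects without a fold assignment: {missing}")
    scores = np.full(len(df), np.nan)
    X = df[list(feature_names)]
    trainable = df["label"].isin(["positive", "negative"]) & ~df["resting"].astype(bool)
    y = (df["label"] == "positive").astype(int).to_numpy()
    for fold in sorted(set(folds.values())):
        train = (fold_of != fold) & trainable
        test = fold_of == fold
        if not test.any():
            continue
        y_tr = y[train.to_numpy()]
        if y_tr.sum() == 0:
            raise ValueError(f"fold {fold}: no positive windows in the training split")
        branches = balanced_bootstrap(y_tr, config.n_branches, seed=seed + 1000 * fold)
        model = train_ensemble(X[train], y_tr, branches, config, seed=seed + 1000 * fold)
        scores[test.to_numpy()] = predict_scores(
            model, X[test], resting_mask=df.loc[test, "resting"].to_numpy()
        )
    out = df.copy()
    out["score"] = scores
    return out


def feature_importance(model: EnsembleModel, top: int | None = None) -> pd.Series:
    """Gain-based importances averaged over branches, normalized to sum 1,
    in descending order."""
    total = np.zeros(len(model.feature_names))
    for clf in model.branches:
        booster = clf.get_booster()
        booster.feature_names = [f"f{i}" for i in range(len(model.feature_names))]
        gains = booster.get_score(importance_type="gain")
        for key, g in gains.items():
            total[int(key[1:])] += g
    if total.sum() > 0:
        total = total / total.sum()
    s = pd.Series(total, index=model.feature_names).sort_values(ascending=False)
    return s.head(top) if top else s


def save_model(model: EnsembleModel, out_dir) -> None:
    """Serialize an ensemble: one JSON booster file per branch plus a
    manifest carrying the feature order, threshold and seed."""
    import json
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for i, clf in enumerate(model.branches):
        clf.get_booster().save_model(str(out / f"branch_{i:03d}.json"))
    manifest = {
        "feature_names": model.feature_names,
        "decision_threshold": model.decision_threshold,
        "training_seed": model.training_seed,
        "n_branches": model.n_branches,
    }
    with open(out / "ensemble.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)


def load_model(model_dir) -> EnsembleModel:
    import json
    from pathlib import Path

    d = Path(model_dir)
    with open(d / "ensemble.json", encoding="utf-8") as fh:
        manifest = json.load(fh)
    branches = []
    for i in range(manifest["n_branches"]):
        clf = XGBClassifier()
        clf.load_model(str(d / f"branch_{i:03d}.json"))
        branches.append(clf)
    return EnsembleModel(
        branches,
        manifest["feature_names"],
        manifest["decision_threshold"],
        manifest["training_seed"],
    )
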