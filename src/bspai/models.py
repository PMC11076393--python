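"""Model bench: seven model configurations, CV evaluation, importances, ranking.

The headline configuration is gradient-boosted trees with a pairwise
(learning-to-rank) objective: ordinal clinical stages induce preferences
(more advanced stage should score higher) and the ranker optimizes pair
order instead of isolated binary labels.  Six pointwise configurations
(logistic regression, decision tree, random forest, gradient boosting, a
fully connected neural net, and pointwise gradient-boosted trees) are kept
for comparison, with fixed published-style hyperparameters.

Evaluation is stratified k-fold cross-validation scored by AUC of the
held-out scores against the binary (approved) label, computed with the
rank-sum formulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.impute import SimpleImputer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier, XGBRanker

from .features import FEATURE_GROUP_ORDER, feature_groups
from .labeling import PairDataset

logger = logging.getLogger("bspai")

MODEL_KINDS = (
    "logistic_regression",
    "decision_tree",
    "random_forest",
    "gradient_boosting",
    "neural_net",
    "gbtree_pointwise",
    "gbtree_pairwise",
)

#: fixed hyperparameters per configuration
DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "logistic_regression": {"C": 0.1, "max_iter": 1000},  # L2 penalty is sklearn's default
    "decision_tree": {"min_samples_leaf": 5, "max_depth": 10},
    "random_forest": {"n_estimators": 100},
    "gradient_boosting": {"learning_rate": 0.1, "n_estimators": 100},
    "neural_net": {
        "hidden_layer_sizes": (256, 128, 64, 32),
        "max_iter": 200,
        "early_stopping": True,
        "validation_fraction": 0.1,
    },
    "gbtree_pointwise": {"learning_rate": 0.1, "n_estimators": 100, "max_depth": 10},
    "gbtree_pairwise": {"learning_rate": 0.1, "n_estimators": 100, "max_depth": 10},
}


@dataclass(frozen=True)
class ModelSpec:
    """A model configuration: kind plus resolved hyperparameters."""

    kind: str
    hyperparams: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}; choose from {MODEL_KINDS}")
        merged = {**DEFAULT_HYPERPARAMS[self.kind], **self.hyperparams}
        object.__setattr__(self, "hyperparams", merged)


@dataclass
class CVResult:
    """Cross-validation outcome for one configuration."""

    spec: ModelSpec
    per_fold_auc: list[float]
    mean_auc: float
    pooled_auc: float
    seed: int
    feature_names: list[str]

    def fold_stderr(self) -> float:
        """Standard error of the per-fold AUC mean."""
        arr = np.asarray(self.per_fold_auc)
        if arr.size < 2:
            return float("nan")
        return float(arr.std(ddof=1) / np.sqrt(arr.size))


def auc_score(labels: np.ndarray, scores: np.ndarray) -> float:
    """AUC via the rank-sum formulation (probability a positive outscores a negative)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


class TargetPairModel(BaseEstimator):
    """One of the seven model configurations behind a uniform fit/score API.

    Parameters
    ----------
    kind : str
        One of :data:`MODEL_KINDS`.
    seed : int
        Random seed for every stochastic component.
    hyperparams : dict, optional
        Overrides merged over the fixed defaults.

    Tree-based kinds consume NaN feature sentinels natively; the other kinds
    impute medians (and standardize for logistic regression / neural net).

    Attributes
    ----------
    estimator_ : fitted underlying estimator (possibly a Pipeline)
    feature_names_ : list of str seen at fit time
    """

    def __init__(self, kind: str = "gbtree_pairwise", seed: int = 0, hyperparams: dict | None = None):
        self.kind = kind
        self.seed = seed
        self.hyperparams = hyperparams

    @property
    def spec(self) -> ModelSpec:
        return ModelSpec(self.kind, self.hyperparams or {})

    @property
    def is_pairwise(self) -> bool:
        return self.kind == "gbtree_pairwise"

    def _build(self):
        hp = self.spec.hyperparams
        if self.kind == "logistic_regression":
            est = LogisticRegression(random_state=self.seed, **hp)
            return Pipeline(
                [
                    ("impute", SimpleImputer(strategy="median")),
                    ("scale", StandardScaler()),
                    ("model", est),
                ]
            )
        if self.kind == "decision_tree":
            est = DecisionTreeClassifier(random_state=self.seed, **hp)
            return Pipeline([("impute", SimpleImputer(strategy="median")), ("model", est)])
        if self.kind == "random_forest":
            est = RandomForestClassifier(random_state=self.seed, n_jobs=1, **hp)
            return Pipeline([("impute", SimpleImputer(strategy="median")), ("model", est)])
        if self.kind == "gradient_boosting":
            est = GradientBoostingClassifier(random_state=self.seed, **hp)
            return Pipeline([("impute", SimpleImputer(strategy="median")), ("model", est)])
        if self.kind == "neural_net":
            est = MLPClassifier(random_state=self.seed, **hp)
            return Pipeline(
                [
                    ("impute", SimpleImputer(strategy="median")),
                    ("scale", StandardScaler()),
                    ("model", est),
                ]
            )
        if self.kind == "gbtree_pointwise":
            return XGBClassifier(
                random_state=self.seed,
                n_jobs=1,
                tree_method="hist",
                eval_metric="logloss",
                **hp,
            )
        if self.kind == "gbtree_pairwise":
            return XGBRanker(
                objective="rank:pairwise",
                random_state=self.seed,
                n_jobs=1,
                tree_method="hist",
                **hp,
            )
        raise ValueError(f"unknown model kind {self.kind!r}")

    def fit(
        self,
        X: pd.DataFrame,
        y: np.ndarray,
        *,
        relevance: np.ndarray | None = None,
        group_ids: np.ndarray | None = None,
    ) -> "TargetPairModel":
        """Fit on a feature table.

        Pointwise kinds use binary ``y`` (needs both classes).  The pairwise
        kind optimizes rank order of ``relevance`` (higher = more advanced
        stage) within ``group_ids`` query groups (one group per fold by
        convention; a single group when not provided).
        """
        X = pd.DataFrame(X)
        self.feature_names_ = list(X.columns)
        est = self._build()
        if self.is_pairwise:
            if relevance is None:
                raise ValueError("pairwise model needs ordinal relevance targets")
            qid = np.zeros(len(X), dtype=int) if group_ids is None else np.asarray(group_ids)
            order = np.argsort(qid, kind="stable")
            est.fit(X.iloc[order], np.asarray(relevance)[order], qid=qid[order])
        else:
            y = np.asarray(y)
            if len(np.unique(y)) < 2:
                raise ValueError("pointwise training needs both classes present")
            est.fit(X, y)
        self.estimator_ = est
        return self

    def decision_function(self, X: pd.DataFrame) -> np.ndarray:
        """Real-valued scores; probabilities for classifiers, raw ranking scores otherwise."""
        X = pd.DataFrame(X)
        if list(X.columns) != self.feature_names_:
            extra = set(X.columns) - set(self.feature_names_)
            missing = set(self.feature_names_) - set(X.columns)
            raise ValueError(
                f"feature columns do not match training: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        if self.is_pairwise:
            return np.asarray(self.estimator_.predict(X), dtype=float)
        return np.asarray(self.estimator_.predict_proba(X)[:, 1], dtype=float)

    predict_score = decision_function


def train(spec: ModelSpec | str, dataset: PairDataset, seed: int | None = None) -> TargetPairModel:
    """Fit one configuration on the full labeled dataset."""
    spec = ModelSpec(spec) if isinstance(spec, str) else spec
    model = TargetPairModel(spec.kind, seed=dataset.seed if seed is None else seed,
                            hyperparams=spec.hyperparams)
    model.fit(
        dataset.X,
        dataset.y,
        relevance=dataset.relevance,
        group_ids=dataset.folds,
    )
    return model


def crossvalidate(
    spec: ModelSpec | str,
    dataset: PairDataset,
    columns: Sequence[str] | None = None,
) -> CVResult:
    """Stratified k-fold CV scored by held-out AUC against the binary label.

    Folds lacking one of the two classes are skipped with a warning; the
    mean is over valid folds.  ``columns`` restricts the feature set (used
    by the ablation protocol).
    """
    spec = ModelSpec(spec) if isinstance(spec, str) else spec
    X = dataset.X if columns is None else dataset.X[list(columns)]
    per_fold: list[float] = []
    pooled_scores = np.empty(len(X))
    pooled_mask = np.zeros(len(X), dtype=bool)
    for f in range(dataset.n_folds):
        test = dataset.folds == f
        train_idx = ~test
        if len(np.unique(dataset.y[test])) < 2:
            logger.warning("fold %d lacks a class; skipped in the fold mean", f)
            continue
        model = TargetPairModel(spec.kind, seed=dataset.seed, hyperparams=spec.hyperparams)
        model.fit(
            X[train_idx],
            dataset.y[train_idx],
            relevance=dataset.relevance[train_idx],
            group_ids=dataset.folds[train_idx],
        )
        scores = model.decision_function(X[test])
        pooled_scores[test] = scores
        pooled_mask[test] = True
        per_fold.append(auc_score(dataset.y[test], scores))
    if not per_fold:
        raise ValueError("no fold had both classes; cannot cross-validate")
    pooled_auc = auc_score(dataset.y[pooled_mask], pooled_scores[pooled_mask])
    return CVResult(
        spec=spec,
        per_fold_auc=per_fold,
        mean_auc=float(np.mean(per_fold)),
        pooled_auc=pooled_auc,
        seed=dataset.seed,
        feature_names=list(X.columns),
    )


# ---------------------------------------------------------------------------
# importances


def feature_frequency_importance(model: TargetPairModel) -> pd.DataFrame:
    """Split-frequency importance: how often each feature is a split node.

    Works for tree-ensemble kinds only; returns a table with columns
    ``count`` (non-negative integers, 0 for never-used features) and
    ``share`` (counts normalized to sum 1), sorted by count descending.
    """
    est = model.estimator_
    if isinstance(est, Pipeline):
        est = est.named_steps["model"]
    names = model.feature_names_
    counts = dict.fromkeys(names, 0)

    if isinstance(est, (XGBClassifier, XGBRanker)):
        for feat, cnt in est.get_booster().get_score(importance_type="weight").items():
            counts[feat] = int(cnt)
    elif isinstance(est, (RandomForestClassifier, GradientBoostingClassifier)):
        trees = [t for row in np.atleast_2d(est.estimators_) for t in np.ravel(row)]
        for t in trees:
            feat_idx = t.tree_.feature
            for j in feat_idx[feat_idx >= 0]:
                counts[names[j]] += 1
    elif isinstance(est, DecisionTreeClassifier):
        feat_idx = est.tree_.feature
        for j in feat_idx[feat_idx >= 0]:
            counts[names[j]] += 1
    else:
        raise TypeError(
            f"split-frequency importance needs a tree ensemble, got {type(est).__name__}"
        )

    table = pd.DataFrame({"feature": names, "count": [counts[n] for n in names]})
    total = table["count"].sum()
    table["share"] = table["count"] / total if total > 0 else 0.0
    return table.sort_values(["count", "feature"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# ablation


def ablation_run(
    dataset: PairDataset,
    group_order: Sequence[str] | None = None,
    spec: ModelSpec | str = "gbtree_pairwise",
) -> list[CVResult]:
    """Cumulative feature-group inclusion, one CV result per prefix.

    Groups are added in ``group_order`` (default: double positive, safety,
    mechanism, embedding, pooled single-cell expression, grouped cell-type
    variants); every prefix uses identical folds and seed.
    """
    group_order = list(group_order or FEATURE_GROUP_ORDER)
    groups = feature_groups(dataset.feature_names())
    unknown = [g for g in group_order if g not in groups]
    if unknown:
        raise ValueError(f"unknown feature groups {unknown}; valid: {sorted(groups)}")
    results = []
    columns: list[str] = []
    for g in group_order:
        columns = columns + groups[g]
        results.append(crossvalidate(spec, dataset, columns=columns))
    return results


# ---------------------------------------------------------------------------
# candidate ranking


def rank_candidates(model: TargetPairModel, candidate_features: pd.DataFrame) -> pd.DataFrame:
    """Score candidates and rank 1-based by descending score.

    Stable sort; ties break by canonical pair order.  Columns must match the
    training feature set exactly.
    """
    scores = model.decision_function(candidate_features)
    out = pd.DataFrame(
        {"pair": candidate_features.index, "score": scores}
    ).sort_values(["score", "pair"], ascending=[False, True], kind="stable")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)
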