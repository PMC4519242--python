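"""Random-forest presence model: fitting, thresholding, validation, importance.

The classifier is a 500-tree random forest with 3 candidate variables per
split, trained on per-cell presence/absence with the 15 landscape
covariates.  The ensemble inducer is scikit-learn's; this module owns the
machinery around it that the analysis actually depends on:

* out-of-bag (OOB) probabilities of presence per cell,
* the equal-sensitivity/specificity cutoff used to turn probabilities into
  a habitat map (a rule that tends to approximate observed prevalence),
* accuracy metrics (PCC, sensitivity, specificity, Cohen's kappa, AUC)
  under resubstitution, OOB and 10-fold cross-validation, and
* the two variable-importance measures (permutation/accuracy importance on
  OOB rows, and Gini impurity importance), standardized to the top
  variable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.utils import check_random_state

from .cover import COVARIATES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ModelConfig:
    n_trees: int = 500
    vars_per_split: int = 3
    seed: int = 0
    threshold_rule: str = "sens_eq_spec"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if not 1 <= self.vars_per_split <= len(COVARIATES):
            raise ValueError(f"vars_per_split must be in [1, {len(COVARIATES)}]")


@dataclass
class AccuracyReport:
    """Classification accuracy at a threshold. Percent scales for PCC/sens/spec."""

    pcc: float
    sensitivity: float
    specificity: float
    kappa: float
    auc: float
    mode: str
    threshold: float

    def as_dict(self) -> dict:
        return {
            "mode": self.mode,
            "threshold": self.threshold,
            "pcc": self.pcc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "kappa": self.kappa,
            "auc": self.auc,
        }


@dataclass
class ThresholdResult:
    threshold: float
    sensitivity: float
    specificity: float
    trace: pd.DataFrame


@dataclass
class FittedHabitatModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    config: ModelConfig
    resub_P: pd.Series
    oob_P: pd.Series
    labels: pd.Series

    def predict_P(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        """Predicted probability of presence for rows of covariates."""
        if isinstance(X, pd.DataFrame):
            X = X[self.feature_names].to_numpy(dtype=float)
        pos = list(self.forest.classes_).index(1)
        return self.forest.predict_proba(X)[:, pos]


def _check_features(table: pd.DataFrame, feature_names: list[str]) -> np.ndarray:
    missing_cols = [c for c in feature_names if c not in table.columns]
    if missing_cols:
        raise ValueError(f"feature table missing covariates: {missing_cols}")
    X = table[feature_names].to_numpy(dtype=float)
    bad = ~np.isfinite(X).all(axis=1)
    if bad.any():
        cells = list(table.index[bad][:10])
        raise ValueError(f"missing covariate values in cells {cells}" + (" ..." if bad.sum() > 10 else ""))
    return X


def fit(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    feature_names: list[str] | None = None,
    label_column: str = "presence",
) -> FittedHabitatModel:
    """Train the presence forest; store resubstitution and OOB probabilities."""
    config = config or ModelConfig()
    feature_names = list(feature_names or COVARIATES)
    X = _check_features(table, feature_names)
    y = table[label_column].to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("degenerate response: both presence and absence cells required")
    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.vars_per_split,
        oob_score=True,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    pos = list(forest.classes_).index(1)
    resub = forest.predict_proba(X)[:, pos]
    oob = forest.oob_decision_function_[:, pos]
    n_nan = int(np.isnan(oob).sum())
    if n_nan:
        logger.warning("%d cells never out-of-bag; filling with resubstitution P", n_nan)
        oob = np.where(np.isnan(oob), resub, oob)
    return FittedHabitatModel(
        forest=forest,
        feature_names=feature_names,
        config=config,
        resub_P=pd.Series(resub, index=table.index, name="resub_P"),
        oob_P=pd.Series(oob, index=table.index, name="oob_P"),
        labels=pd.Series(y, index=table.index, name=label_column),
    )


def auc_score(labels: np.ndarray, probabilities: np.ndarray) -> float:
    """AUC as the Mann–Whitney rank statistic with midranks for ties."""
    labels = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC needs both classes")
    ranks = rankdata(p)
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def accuracy_metrics(
    labels: np.ndarray,
    probabilities: np.ndarray,
    threshold: float,
    mode: str = "resubstitution",
    predicted: np.ndarray | None = None,
) -> AccuracyReport:
    """PCC / sensitivity / specificity (percent), Cohen's kappa, AUC.

    Classification is ``P >= threshold``; ``predicted`` can override the
    thresholded classes (used when pooling CV folds with per-fold cutoffs),
    in which case AUC still comes from the raw probabilities.
    """
    labels = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    if len(labels) == 0:
        raise ValueError("empty evaluation set")
    if not ((labels == 0) | (labels == 1)).all():
        raise ValueError("labels must be 0/1")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    pred = (p >= threshold).astype(int) if predicted is None else np.asarray(predicted, dtype=int)
    n = len(labels)
    tp = int(((pred == 1) & (labels == 1)).sum())
    tn = int(((pred == 0) & (labels == 0)).sum())
    fp = int(((pred == 1) & (labels == 0)).sum())
    fn = int(((pred == 0) & (labels == 1)).sum())
    n1, n0 = tp + fn, tn + fp
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    pcc = 100.0 * (tp + tn) / n
    sens = 100.0 * tp / n1
    spec = 100.0 * tn / n0
    p_o = (tp + tn) / n
    p_e = ((tp + fp) * n1 + (fn + tn) * n0) / n**2
    kappa = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 else 1.0
    return AccuracyReport(
        pcc=pcc,
        sensitivity=sens,
        specificity=spec,
        kappa=float(kappa),
        auc=auc_score(labels, p),
        mode=mode,
        threshold=float(threshold),
    )


def select_threshold(labels: np.ndarray, probabilities: np.ndarray) -> ThresholdResult:
    """Cutoff where sensitivity equals specificity (as nearly as possible).

    Candidates are the sorted unique probabilities; the selected threshold
    minimises |sens - spec|, breaking ties toward the smaller threshold
    (favouring sensitivity).  This rule tends to classify a fraction of
    cells as present close to the observed prevalence.
    """
    labels = np.asarray(labels, dtype=int)
    p = np.asarray(probabilities, dtype=float)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present to select a threshold")
    cand = np.unique(p)
    pos_sorted = np.sort(p[labels == 1])
    neg_sorted = np.sort(p[labels == 0])
    # counts with P >= t via binary search on sorted class scores
    tp = n1 - np.searchsorted(pos_sorted, cand, side="left")
    fp = n0 - np.searchsorted(neg_sorted, cand, side="left")
    sens = 100.0 * tp / n1
    spec = 100.0 * (n0 - fp) / n0
    gap = np.abs(sens - spec)
    best = int(np.argmin(gap))  # argmin returns the first (smallest t) on ties
    trace = pd.DataFrame({"threshold": cand, "sensitivity": sens, "specificity": spec})
    return ThresholdResult(
        threshold=float(cand[best]),
        sensitivity=float(sens[best]),
        specificity=float(spec[best]),
        trace=trace,
    )


def _fold_assignments(n: int, k: int, seed: int, y: np.ndarray, max_tries: int = 20) -> np.ndarray:
    """Seeded random partition into k near-equal folds; every training set
    must contain both classes (refold with a new seed otherwise, logged)."""
    for attempt in range(max_tries):
        rng = np.random.default_rng(seed + attempt)
        order = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[order] = np.arange(n) % k
        ok = all(len(np.unique(y[folds != f])) == 2 for f in range(k))
        if ok:
            if attempt:
                logger.info("refolded %d times to keep both classes in training", attempt)
            return folds
    raise ValueError("could not build folds with both classes in every training set")


def cross_validate(
    table: pd.DataFrame,
    config: ModelConfig | None = None,
    k: int = 10,
    feature_names: list[str] | None = None,
    label_column: str = "presence",
) -> dict:
    """k-fold cross-validation with the threshold re-derived per fold.

    Each fold is predicted by a forest trained on the other k-1 folds; the
    equal-sens/spec threshold is selected inside each training set (from
    that model's OOB probabilities) to avoid information leakage.  Metrics
    are computed on the pooled held-out predictions; per-fold means and a
    pooled re-derived threshold are also reported.
    """
    config = config or ModelConfig()
    feature_names = list(feature_names or COVARIATES)
    X = _check_features(table, feature_names)
    y = table[label_column].to_numpy(dtype=int)
    n = len(y)
    if n < k:
        raise ValueError(f"need at least k={k} rows")
    folds = _fold_assignments(n, k, config.seed, y)
    pooled_p = np.empty(n)
    pooled_pred = np.empty(n, dtype=int)
    fold_rows = []
    for f in range(k):
        test = folds == f
        train = ~test
        forest = RandomForestClassifier(
            n_estimators=config.n_trees,
            max_features=config.vars_per_split,
            oob_score=True,
            bootstrap=True,
            random_state=config.seed + f,
            n_jobs=1,
        )
        forest.fit(X[train], y[train])
        pos = list(forest.classes_).index(1)
        oob_train = forest.oob_decision_function_[:, pos]
        if np.isnan(oob_train).any():
            oob_train = np.where(
                np.isnan(oob_train), forest.predict_proba(X[train])[:, pos], oob_train
            )
        t_fold = select_threshold(y[train], oob_train).threshold
        p_test = forest.predict_proba(X[test])[:, pos]
        pooled_p[test] = p_test
        pooled_pred[test] = (p_test >= t_fold).astype(int)
        if len(np.unique(y[test])) == 2:
            fold_rows.append(
                accuracy_metrics(y[test], p_test, t_fold, mode=f"fold_{f}").as_dict()
            )
    pooled_threshold = select_threshold(y, pooled_p).threshold
    pooled = accuracy_metrics(
        y, pooled_p, pooled_threshold, mode=f"cv{k}", predicted=pooled_pred
    )
    per_fold = pd.DataFrame(fold_rows)
    return {
        "pooled": pooled,
        "pooled_threshold": pooled_threshold,
        "per_fold": per_fold,
        "per_fold_mean": per_fold[["pcc", "sensitivity", "specificity", "kappa", "auc"]].mean().to_dict()
        if len(per_fold)
        else {},
        "held_out_P": pd.Series(pooled_p, index=table.index, name="cv_P"),
        "folds": pd.Series(folds, index=table.index, name="fold"),
    }


def _oob_masks(forest: RandomForestClassifier, n: int) -> np.ndarray:
    """(n_trees, n) boolean matrix of out-of-bag rows per tree.

    Reproduces the bootstrap draw scikit-learn makes for each tree (one
    uniform draw of n sample indices seeded by the tree's random_state).
    """
    masks = np.empty((len(forest.estimators_), n), dtype=bool)
    for t, tree in enumerate(forest.estimators_):
        rnd = check_random_state(tree.random_state)
        sampled = rnd.randint(0, n, n)
        masks[t] = np.bincount(sampled, minlength=n) == 0
    return masks


def variable_importance(
    model: FittedHabitatModel,
    table: pd.DataFrame,
    n_permutations: int = 10,
) -> pd.DataFrame:
    """Accuracy (OOB permutation) and Gini importance, standardized to max 1.

    Accuracy importance for variable j is the mean, over trees and seeded
    permutation replicates, of the drop in that tree's OOB accuracy when
    column j is permuted.  Gini importance is the forest's mean decrease in
    node impurity.  Both are rescaled so the top variable scores 1; the
    combined rank orders variables by the sum of the two standardized
    scores.
    """
    X = table[model.feature_names].to_numpy(dtype=float)
    y = model.labels.to_numpy(dtype=int)
    n, p = X.shape
    forest = model.forest
    masks = _oob_masks(forest, n)
    rng = np.random.default_rng(model.config.seed + 987_001)

    # baseline per-tree OOB accuracy
    base_acc = np.empty(len(forest.estimators_))
    for t, tree in enumerate(forest.estimators_):
        pred = tree.predict(X).astype(int)
        m = masks[t]
        base_acc[t] = (pred[m] == y[m]).mean() if m.any() else np.nan

    perms = [rng.permutation(n) for _ in range(n_permutations)]
    acc_imp = np.zeros(p)
    for j in range(p):
        # stack all permutation replicates so each tree predicts once
        stacked = np.tile(X, (n_permutations, 1))
        for r, perm in enumerate(perms):
            stacked[r * n : (r + 1) * n, j] = X[perm, j]
        drops = []
        for t, tree in enumerate(forest.estimators_):
            m = masks[t]
            if not m.any():
                continue
            pred = tree.predict(stacked).astype(int).reshape(n_permutations, n)
            acc = (pred[:, m] == y[m]).mean(axis=1)
            drops.append(base_acc[t] - acc.mean())
        acc_imp[j] = float(np.mean(drops))
    gini_imp = forest.feature_importances_.copy()

    def standardize(v: np.ndarray) -> np.ndarray:
        top = np.max(v)
        return v / top if top > 0 else np.zeros_like(v)

    acc_std = standardize(acc_imp)
    gini_std = standardize(gini_imp)
    combined = acc_std + gini_std
    order = np.argsort(-combined, kind="stable")
    rank = np.empty(p, dtype=int)
    rank[order] = np.arange(1, p + 1)
    return pd.DataFrame(
        {
            "accuracy_importance": acc_imp,
            "gini_importance": gini_imp,
            "accuracy_std": acc_std,
            "gini_std": gini_std,
            "combined_score": combined,
            "rank": rank,
        },
        index=pd.Index(model.feature_names, name="variable"),
    ).sort_values("rank")
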