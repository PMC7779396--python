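"""Comparator models: linear-kernel SVR score prediction and SVM classification.

The SVR comparator keeps the nested CPM edge-selection step but feeds the
selected edges' individual Fisher-z values (positive and negative tails
pooled) into a linear support vector regression instead of summing them.
The SVM comparator classifies case vs control from all upper-triangle edge
features under stratified cross-validation, reporting balanced accuracy
(mean of sensitivity and specificity) and a per-edge mean |weight| map for
region-level interpretation.

Hyperparameters follow common practice where the protocol is underspecified:
C = 1 with within-fold feature standardization for both models.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC, SVR

from .core import _critical_rho, _rank_normalize, _safe_rho, perm_pvalue
from .types import (
    ClassificationReport,
    Cohort,
    InvalidParameterError,
    NodeAtlas,
)

logger = logging.getLogger(__name__)


@dataclass
class SVRReport:
    """Leave-one-out SVR predictions with CPM-style edge selection."""

    predicted: np.ndarray
    observed: np.ndarray
    rho_pred_obs: float
    per_fold_n_features: list[int]
    p_perm: float | None = None
    null_rhos: np.ndarray | None = None


def _loo_svr_predictions(Z: np.ndarray, y: np.ndarray, threshold: float, C: float):
    """One full LOOCV pass: nested selection, standardized features, linear SVR."""
    n = Z.shape[0]
    rho_crit = _critical_rho(n - 1, threshold)
    predicted = np.empty(n)
    n_features = []
    for i in range(n):
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Zt = Z[idx]
        rho = _rank_normalize(Zt).T @ _rank_normalize(y[idx, None])[:, 0]
        mask = np.abs(rho) > rho_crit  # both tails pooled as features
        n_features.append(int(mask.sum()))
        if not mask.any():
            predicted[i] = float(y[idx].mean())
            continue
        scaler = StandardScaler().fit(Zt[:, mask])
        model = SVR(kernel="linear", C=C)
        model.fit(scaler.transform(Zt[:, mask]), y[idx])
        predicted[i] = float(model.predict(scaler.transform(Z[i : i + 1, mask]))[0])
    return predicted, n_features


def svr_predict(
    cohort: Cohort,
    threshold: float = 0.05,
    C: float = 1.0,
    n_perm: int = 0,
    seed: int = 0,
) -> SVRReport:
    """Linear-kernel SVR on per-edge z-values selected the CPM way.

    Within each leave-one-out fold, edges are selected exactly as in the
    CPM procedure; the held-out subject is predicted from its standardized
    selected-edge values. Performance is the Spearman rho between predicted
    and observed scores. If ``n_perm`` > 0, a one-sided permutation p is
    computed by re-running the whole nested procedure on shuffled scores.
    """
    n = cohort.n_subjects
    if n < 10:
        raise InvalidParameterError(f"LOOCV needs >= 10 subjects, got {n}")
    Z = cohort.edge_matrix()
    y = cohort.scores
    predicted, n_features = _loo_svr_predictions(Z, y, threshold, C)
    if not any(n_features):
        logger.info("no edges selected in any fold; all predictions are training means")
    observed_rho = _safe_rho(predicted, y)

    p_perm = None
    null_rhos = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null_rhos = np.empty(n_perm)
        for b in range(n_perm):
            yb = y[rng.permutation(n)]
            pred_b, _ = _loo_svr_predictions(Z, yb, threshold, C)
            null_rhos[b] = _safe_rho(pred_b, yb)
        p_perm = perm_pvalue(null_rhos, observed_rho)

    return SVRReport(
        predicted=predicted,
        observed=y,
        rho_pred_obs=observed_rho,
        per_fold_n_features=n_features,
        p_perm=p_perm,
        null_rhos=null_rhos,
    )


def _pooled_confusion_rates(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float]:
    """(sensitivity, specificity) from pooled out-of-fold predictions; 1 = case."""
    pos = y_true == 1
    sens = float(np.mean(y_pred[pos] == 1)) if pos.any() else 0.0
    spec = float(np.mean(y_pred[~pos] == 0)) if (~pos).any() else 0.0
    return sens, spec


def _cv_svm_balanced_accuracy(
    X: np.ndarray, y: np.ndarray, n_folds: int, seed: int, C: float,
    collect_weights: bool = False,
):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y_pred = np.empty_like(y)
    weights = []
    for train_idx, test_idx in skf.split(X, y):
        scaler = StandardScaler().fit(X[train_idx])
        model = SVC(kernel="linear", C=C)
        model.fit(scaler.transform(X[train_idx]), y[train_idx])
        y_pred[test_idx] = model.predict(scaler.transform(X[test_idx]))
        if collect_weights:
            weights.append(np.abs(model.coef_[0]))
    sens, spec = _pooled_confusion_rates(y, y_pred)
    weight_map = np.mean(weights, axis=0) if weights else None
    return (sens + spec) / 2.0, sens, spec, weight_map


def svm_classify(
    cohort: Cohort,
    n_folds: int = 10,
    seed: int = 0,
    C: float = 1.0,
    n_perm: int = 0,
    atlas: NodeAtlas | None = None,
    top_k: int = 10,
) -> ClassificationReport:
    """Stratified cross-validated linear SVM on upper-triangle edge features.

    Sensitivity and specificity come from pooled out-of-fold predictions
    (label 1 = case); balanced accuracy is their mean. ``weight_map`` is the
    mean absolute linear-SVM weight per edge across folds; with an atlas it
    is aggregated to node level (summed |w| over incident edges) and the
    top-k node labels are reported. If ``n_perm`` > 0, significance is
    assessed by re-running the cross-validation on shuffled labels.
    """
    if cohort.labels is None:
        raise InvalidParameterError("cohort has no diagnosis labels")
    y = cohort.labels
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise InvalidParameterError(f"need exactly two classes, got {classes.tolist()}")
    if counts.min() < 5:
        raise InvalidParameterError("each class needs >= 5 members")
    if n_folds > counts.min():
        raise InvalidParameterError("n_folds exceeds the smaller class size")
    if not np.array_equal(np.sort(classes), [0, 1]):
        raise InvalidParameterError("labels must be coded 0 (control) / 1 (case)")

    X = cohort.edge_matrix()
    bal, sens, spec, weight_map = _cv_svm_balanced_accuracy(
        X, y, n_folds, seed, C, collect_weights=True
    )

    top_regions: list[str] = []
    if atlas is not None:
        if atlas.n_nodes != cohort.n_nodes:
            raise InvalidParameterError("atlas and cohort disagree on node count")
        iu, ju = np.triu_indices(cohort.n_nodes, k=1)
        node_w = np.zeros(cohort.n_nodes)
        np.add.at(node_w, iu, weight_map)
        np.add.at(node_w, ju, weight_map)
        order = np.lexsort((np.arange(cohort.n_nodes), -node_w))[:top_k]
        top_regions = [str(atlas.regions()[i]) for i in order]

    p_perm = None
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        null = np.empty(n_perm)
        for b in range(n_perm):
            yb = y[rng.permutation(y.size)]
            null[b], *_ = _cv_svm_balanced_accuracy(X, yb, n_folds, seed, C)
        p_perm = perm_pvalue(null, bal)

    return ClassificationReport(
        balanced_accuracy=bal,
        sensitivity=sens,
        specificity=spec,
        weight_map=weight_map,
        top_regions=top_regions,
        p_perm=p_perm,
    )
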