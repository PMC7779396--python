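"""Connectome-based predictive modeling: selection, LOOCV, permutation inference.

The procedure, per leave-one-out fold: (1) Spearman-correlate every
upper-triangle edge weight with the behavior score across the training
subjects and keep edges with two-sided p below the threshold, split by the
sign of rho into a positive and a negative predictive network; (2) summarize
each training subject by the summed Fisher-z strength over each network;
(3) fit an ordinary least-squares line from strength to score; (4) predict
the held-out subject from its own network strength. Model performance is
the Spearman correlation between cross-validated predictions and observed
scores, and significance comes from re-running the whole nested procedure
on score-shuffled data (one-sided permutation p, ``(k + 1) / (n_perm + 1)``).

Implementation notes
--------------------
Edge-wise Spearman correlations are computed in bulk: ranks of the training
edge matrix depend only on which subject is held out, not on the scores, so
each fold reduces to one matrix product between centered, normalized rank
matrices. The p < threshold rule is applied as an exactly equivalent
critical value on |rho| (the t-approximation p is strictly monotone in |rho|
for fixed n), which lets a permutation test evaluate all shuffles per fold
with a single GEMM. Per-edge p-values use the t-distribution approximation
with average ranks for ties, as exact permutation p per edge is infeasible
at tens of thousands of edges per fold.
"""

from __future__ import annotations

import logging
import warnings
from concurrent.futures import ThreadPoolExecutor
from typing import Optional

import numpy as np
from scipy import stats

from .types import (
    Cohort,
    ConnectivityMatrix,
    CPMModel,
    CPMResult,
    DegenerateInputError,
    Edge,
    EdgeSelection,
    InvalidParameterError,
    PermutationResult,
)

logger = logging.getLogger(__name__)

__all__ = [
    "select_edges",
    "network_strength",
    "fit_linear",
    "loocv",
    "loocv_fixed_selection",
    "kfold_cv",
    "evaluate",
    "permutation_test",
    "perm_pvalue",
    "covariate_screen",
]


# ---------------------------------------------------------------------------
# Spearman machinery


def _rank_normalize(x: np.ndarray) -> np.ndarray:
    """Average ranks along axis 0, centered and scaled to unit norm per column.

    Columns with zero rank variance (constant input) become all-zero, so any
    correlation against them is 0.
    """
    r = stats.rankdata(x, axis=0)
    r -= r.mean(axis=0)
    norms = np.linalg.norm(r, axis=0)
    norms = np.where(norms == 0.0, np.inf, norms)
    return r / norms


def _spearman_p(rho: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t-distribution approximation, df = n - 2."""
    rho = np.clip(rho, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
    at_unit = np.abs(rho) >= 1.0
    if np.any(at_unit):
        t = np.where(at_unit, np.sign(rho) * np.finfo(float).max, t)
    return 2.0 * stats.t.sf(np.abs(t), df=n - 2)


def _critical_rho(n: int, threshold: float) -> float:
    """|rho| above which the two-sided t-approximation p falls below threshold."""
    t_crit = stats.t.isf(threshold / 2.0, df=n - 2)
    return float(t_crit / np.sqrt(n - 2 + t_crit**2))


def _edges_from_mask(mask: np.ndarray, iu: np.ndarray, ju: np.ndarray) -> set[Edge]:
    idx = np.flatnonzero(mask)
    return set(zip(iu[idx].tolist(), ju[idx].tolist()))


# ---------------------------------------------------------------------------
# Public operations


def select_edges(train: Cohort, threshold: float = 0.05) -> EdgeSelection:
    """Spearman-correlate every edge with the score; partition by rho sign.

    Edges with two-sided p strictly below ``threshold`` are selected;
    positive-rho edges form the positive predictive network, negative-rho
    edges the negative one. Ties are handled with average ranks.
    """
    if not 0.0 < threshold < 1.0:
        raise InvalidParameterError("threshold must be in (0, 1)")
    n = train.n_subjects
    if n < 5:
        raise InvalidParameterError(f"need >= 5 training subjects, got {n}")
    if np.ptp(train.scores) == 0:
        raise DegenerateInputError("score vector is constant; ranks undefined")

    Z = train.edge_matrix()
    Rn = _rank_normalize(Z)
    sn = _rank_normalize(train.scores[:, None])[:, 0]
    rho = Rn.T @ sn
    p = _spearman_p(rho, n)

    iu, ju = np.triu_indices(train.n_nodes, k=1)
    sig = p < threshold
    return EdgeSelection(
        positive_edges=_edges_from_mask(sig & (rho > 0), iu, ju),
        negative_edges=_edges_from_mask(sig & (rho < 0), iu, ju),
        rho=rho,
        p=p,
        threshold=threshold,
        n_nodes=train.n_nodes,
    )


def network_strength(m: ConnectivityMatrix, edges: set[Edge]) -> float:
    """Sum of Fisher-z weights over an edge set; empty set -> 0."""
    total = 0.0
    n = m.n_nodes
    for i, j in edges:
        if not (0 <= i < n and 0 <= j < n):
            raise InvalidParameterError(f"edge ({i},{j}) outside a {n}-node matrix")
        total += m.z[i, j]
    return float(total)


def fit_linear(strengths: np.ndarray, scores: np.ndarray) -> tuple[float, float]:
    """Degree-1 ordinary least squares of score on network strength.

    Constant strengths leave the slope undefined; the fallback is slope 0
    and intercept = mean score (i.e., predict the training mean), logged.
    """
    strengths = np.asarray(strengths, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if strengths.shape != scores.shape or strengths.size < 2:
        raise InvalidParameterError("need equal-length vectors of size >= 2")
    sc = strengths - strengths.mean()
    den = float(sc @ sc)
    if den < 1e-12:
        logger.warning("constant network strengths: falling back to mean-score model")
        return 0.0, float(scores.mean())
    slope = float(sc @ (scores - scores.mean())) / den
    return slope, float(scores.mean() - slope * strengths.mean())


def evaluate(predicted: np.ndarray, observed: np.ndarray) -> float:
    """Spearman rank correlation between predicted and observed scores."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.size < 3:
        raise InvalidParameterError("need equal-length vectors of size >= 3")
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        raise DegenerateInputError("correlation undefined for a constant vector")
    rho, _ = stats.spearmanr(predicted, observed)
    return float(rho)


def _safe_rho(predicted: np.ndarray, observed: np.ndarray) -> float:
    """evaluate(), but a constant prediction vector scores 0 instead of erroring.

    Inside cross-validation a constant prediction (every fold fell back to
    the training mean) carries no ordering information, so its rank
    correlation is treated as 0.
    """
    if np.ptp(predicted) == 0 or np.ptp(observed) == 0:
        return 0.0
    rho, _ = stats.spearmanr(predicted, observed)
    return float(rho)


# ---------------------------------------------------------------------------
# Cross-validation core


def _batched_loo_predict(
    Z: np.ndarray,
    Y: np.ndarray,
    threshold: float,
    collect_edges: bool = False,
    threads: int = 1,
):
    """Leave-one-out CPM predictions for many score columns at once.

    Z is the (n_subjects x n_edges) Fisher-z edge matrix; Y is
    (n_subjects x k) with one score vector per column (column 0 is the
    observed scores; further columns are typically permutations). For each
    fold the training edge ranks are shared by all columns, so edge-wise
    Spearman rho for every column is one matrix product. Returns
    ``(pred_pos, pred_neg, fold_masks)`` where predictions are (n x k) and
    ``fold_masks`` (if requested) is a list of (pos_mask, neg_mask) boolean
    edge arrays for column 0 of each fold.
    """
    n, n_edges = Z.shape
    k = Y.shape[1]
    rho_crit = _critical_rho(n - 1, threshold)
    pred_pos = np.empty((n, k))
    pred_neg = np.empty((n, k))
    fold_masks: list[tuple[np.ndarray, np.ndarray]] = [None] * n if collect_edges else []
    empty_folds = 0

    def run_fold(i: int) -> int:
        nonlocal fold_masks
        idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
        Zt = Z[idx]
        Rn = _rank_normalize(Zt)              # (n-1, E)
        Sn = _rank_normalize(Y[idx])          # (n-1, k)
        rho = Rn.T @ Sn                        # (E, k)
        pos = (rho > rho_crit)
        neg = (rho < -rho_crit)
        if collect_edges:
            fold_masks[i] = (pos[:, 0].copy(), neg[:, 0].copy())
        empties = 0
        yt = Y[idx]
        ym = yt.mean(axis=0)
        ytc = yt - ym
        for mask, pred in ((pos, pred_pos), (neg, pred_neg)):
            maskf = mask.astype(float)
            st = Zt @ maskf                    # (n-1, k) training strengths
            s_test = Z[i] @ maskf              # (k,)
            sm = st.mean(axis=0)
            stc = st - sm
            den = np.einsum("ij,ij->j", stc, stc)
            ok = den > 1e-12
            slope = np.zeros(k)
            slope[ok] = np.einsum("ij,ij->j", stc[:, ok], ytc[:, ok]) / den[ok]
            intercept = ym - slope * sm
            pred[i] = intercept + slope * s_test
            empties += int(np.sum(mask.sum(axis=0) == 0))
        return empties

    if threads > 1:
        with ThreadPoolExecutor(max_workers=threads) as pool:
            empty_folds = sum(pool.map(run_fold, range(n)))
    else:
        for i in range(n):
            empty_folds += run_fold(i)

    if empty_folds:
        logger.info(
            "%d fold/column tail(s) selected zero edges; predicted training mean",
            empty_folds,
        )
    return pred_pos, pred_neg, fold_masks


def _result_from_predictions(
    tail: str,
    predicted: np.ndarray,
    observed: np.ndarray,
    fold_masks: list,
    which: int,
    iu: np.ndarray,
    ju: np.ndarray,
) -> CPMResult:
    per_fold = [_edges_from_mask(masks[which], iu, ju) for masks in fold_masks]
    contributing = set.intersection(*per_fold) if per_fold else set()
    return CPMResult(
        tail=tail,
        predicted=predicted,
        observed=observed,
        rho_pred_obs=_safe_rho(predicted, observed),
        per_fold_edges=per_fold,
        contributing_edges=contributing,
    )


def loocv(
    cohort: Cohort,
    threshold: float = 0.05,
    threads: int = 1,
) -> tuple[CPMResult, CPMResult]:
    """Nested leave-one-out CPM; returns (positive-tail, negative-tail) results.

    Edge selection is redone inside every fold on the n-1 training subjects
    (no leakage of the held-out subject into selection). A fold whose tail
    selects zero edges predicts the training-set mean score for that
    subject. ``contributing_edges`` is the strict intersection of the
    per-fold selections — the edges that appear in every iteration.
    """
    n = cohort.n_subjects
    if n < 10:
        raise InvalidParameterError(f"LOOCV needs >= 10 subjects, got {n}")
    if np.ptp(cohort.scores) == 0:
        raise DegenerateInputError("score vector is constant")
    Z = cohort.edge_matrix()
    Y = cohort.scores[:, None]
    pred_pos, pred_neg, fold_masks = _batched_loo_predict(
        Z, Y, threshold, collect_edges=True, threads=threads
    )
    iu, ju = np.triu_indices(cohort.n_nodes, k=1)
    pos = _result_from_predictions("positive", pred_pos[:, 0], cohort.scores, fold_masks, 0, iu, ju)
    neg = _result_from_predictions("negative", pred_neg[:, 0], cohort.scores, fold_masks, 1, iu, ju)
    return pos, neg


def loocv_fixed_selection(
    cohort: Cohort, selection: EdgeSelection
) -> tuple[CPMResult, CPMResult]:
    """LOOCV of the linear fit only, with edges pre-selected outside the loop.

    This deliberately leaks the held-out subject into edge selection when
    ``selection`` was computed on the full cohort. It exists as the
    comparison arm for demonstrating selection leakage: on null data its
    predicted-vs-observed rho is optimistically biased, whereas the nested
    ``loocv`` stays centered at zero. Not for substantive use.
    """
    n = cohort.n_subjects
    if n < 10:
        raise InvalidParameterError(f"LOOCV needs >= 10 subjects, got {n}")
    results = []
    for tail, edges in (("positive", selection.positive_edges),
                        ("negative", selection.negative_edges)):
        predicted = np.empty(n)
        for i in range(n):
            idx = np.concatenate([np.arange(i), np.arange(i + 1, n)])
            strengths = np.array(
                [network_strength(cohort.subjects[t], edges) for t in idx]
            )
            if edges and np.ptp(strengths) > 0:
                slope, intercept = fit_linear(strengths, cohort.scores[idx])
            else:
                slope, intercept = 0.0, float(cohort.scores[idx].mean())
            predicted[i] = intercept + slope * network_strength(cohort.subjects[i], edges)
        results.append(
            CPMResult(
                tail=tail,
                predicted=predicted,
                observed=cohort.scores,
                rho_pred_obs=_safe_rho(predicted, cohort.scores),
                per_fold_edges=[set(edges)] * n,
                contributing_edges=set(edges),
            )
        )
    return results[0], results[1]


def kfold_cv(
    cohort: Cohort, threshold: float = 0.05, k: int = 10, seed: int = 0
) -> tuple[CPMResult, CPMResult]:
    """k-fold variant of the nested procedure (provided as an option;
    the validated protocol is leave-one-out)."""
    n = cohort.n_subjects
    if not 2 <= k <= n:
        raise InvalidParameterError(f"k must be in [2, {n}]")
    if k == n:
        return loocv(cohort, threshold)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    folds = np.array_split(order, k)
    Z = cohort.edge_matrix()
    iu, ju = np.triu_indices(cohort.n_nodes, k=1)
    rho_crit = None
    pred = {"positive": np.empty(n), "negative": np.empty(n)}
    per_fold = {"positive": [], "negative": []}
    for test_idx in folds:
        train_idx = np.setdiff1d(order, test_idx)
        Zt = Z[train_idx]
        rho_crit = _critical_rho(len(train_idx), threshold)
        Rn = _rank_normalize(Zt)
        sn = _rank_normalize(cohort.scores[train_idx][:, None])[:, 0]
        rho = Rn.T @ sn
        for tail, mask in (("positive", rho > rho_crit), ("negative", rho < -rho_crit)):
            per_fold[tail].append(_edges_from_mask(mask, iu, ju))
            st = Zt @ mask.astype(float)
            if mask.any() and np.ptp(st) > 0:
                slope, intercept = fit_linear(st, cohort.scores[train_idx])
            else:
                slope, intercept = 0.0, float(cohort.scores[train_idx].mean())
            pred[tail][test_idx] = intercept + slope * (Z[test_idx] @ mask.astype(float))
    out = []
    for tail in ("positive", "negative"):
        out.append(
            CPMResult(
                tail=tail,
                predicted=pred[tail],
                observed=cohort.scores,
                rho_pred_obs=_safe_rho(pred[tail], cohort.scores),
                per_fold_edges=per_fold[tail],
                contributing_edges=set.intersection(*per_fold[tail]),
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Permutation inference


def perm_pvalue(null_stats: np.ndarray, observed: float) -> float:
    """One-sided permutation p: (#{null >= observed} + 1) / (n_perm + 1).

    With 1,000 shuffles and an observed statistic exceeding every null this
    floors at 1/1001, which rounds to 0.001.
    """
    null_stats = np.asarray(null_stats, dtype=float)
    return float((np.sum(null_stats >= observed) + 1) / (null_stats.size + 1))


def permutation_test(
    cohort: Cohort,
    threshold: float = 0.05,
    n_perm: int = 1000,
    seed: int = 0,
    threads: int = 1,
) -> tuple[PermutationResult, PermutationResult]:
    """Permutation inference for both tails by score shuffling.

    The score-to-matrix correspondence is shuffled ``n_perm`` times and the
    full nested LOOCV (edge selection included) is re-run on each shuffle;
    the null statistic is the predicted-vs-observed Spearman rho. Covariates
    and labels travel with the scores conceptually but play no role in the
    model, so only scores are permuted. One-sided toward positive rho.
    """
    if n_perm < 100:
        raise InvalidParameterError("n_perm must be >= 100")
    n = cohort.n_subjects
    rng = np.random.default_rng(seed)
    Z = cohort.edge_matrix()
    Y = np.empty((n, n_perm + 1))
    Y[:, 0] = cohort.scores
    for b in range(n_perm):
        Y[:, b + 1] = cohort.scores[rng.permutation(n)]

    pred_pos, pred_neg, _ = _batched_loo_predict(Z, Y, threshold, threads=threads)

    out = []
    for tail, pred in (("positive", pred_pos), ("negative", pred_neg)):
        rhos = np.array([_safe_rho(pred[:, b], Y[:, b]) for b in range(n_perm + 1)])
        observed, null = float(rhos[0]), rhos[1:]
        out.append(
            PermutationResult(
                tail=tail,
                null_rhos=null,
                observed_rho=observed,
                p_perm=perm_pvalue(null, observed),
                n_perm=n_perm,
            )
        )
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Preliminary screens


def covariate_screen(cohort: Cohort) -> dict:
    """Score-vs-covariate screens: Pearson r with age and mean FD, rank-sum by sex.

    Missing covariates are omitted from the report with a warning rather
    than raised, since they are optional cohort metadata.
    """
    report: dict[str, float] = {}
    cov = cohort.covariates
    if cov is None:
        warnings.warn("no covariates present; empty screen", stacklevel=2)
        return report
    scores = cohort.scores
    for col, (rkey, pkey) in (("age", ("rho_age", "p_age")),
                              ("mean_fd", ("rho_fd", "p_fd"))):
        if col in cov.columns and cov[col].notna().all():
            r, p = stats.pearsonr(scores, cov[col].to_numpy(dtype=float))
            report[rkey], report[pkey] = float(r), float(p)
        else:
            warnings.warn(f"covariate '{col}' missing; omitted from screen", stacklevel=2)
    if "sex" in cov.columns and cov["sex"].notna().all():
        groups = cov["sex"].astype(str).to_numpy()
        levels = np.unique(groups)
        if levels.size == 2:
            a = scores[groups == levels[0]]
            b = scores[groups == levels[1]]
            stat = stats.mannwhitneyu(a, b, alternative="two-sided")
            report["sex_test_p"] = float(stat.pvalue)
        else:
            warnings.warn(
                f"sex has {levels.size} level(s); two-group comparison omitted",
                stacklevel=2,
            )
    else:
        warnings.warn("covariate 'sex' missing; omitted from screen", stacklevel=2)
    return report


def build_model(train: Cohort, edges: set[Edge], tail: str) -> CPMModel:
    """Fit one tail's strength->score line on a training cohort."""
    strengths = np.array([network_strength(m, edges) for m in train.subjects])
    slope, intercept = fit_linear(strengths, train.scores) if np.ptp(strengths) > 0 else (
        0.0, float(train.scores.mean())
    )
    return CPMModel(tail=tail, edges=set(edges), slope=slope, intercept=intercept)
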