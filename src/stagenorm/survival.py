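"""Lasso-Cox gene selection, risk scores, Kaplan-Meier curves, log-rank.

An L1-penalized Cox proportional-hazards model (glmnet-style
coordinate-descent path) selects prognostic genes from the normalized
expression of a sample subset.  The penalty strength is chosen by
k-fold cross-validated partial-likelihood deviance (Verweij & van
Houwelingen form) at its minimum.  Each patient's risk score is the
inner product of the nonzero coefficients with their expression;
patients are split at the median score (ties to the low-risk group) and
the two groups' Kaplan-Meier curves are compared with a log-rank test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv

logger = logging.getLogger(__name__)


@dataclass
class SurvivalResult:
    """Artifacts of one risk-score survival analysis."""

    selected_genes: dict[str, float]
    risk_score: pd.Series
    median_risk: float
    group: pd.Series  # 1 = high risk-score, 0 = at or below median
    km_curves: dict[int, pd.DataFrame]
    logrank_statistic: float
    logrank_p: float
    lambda_: float
    seed: int


def _breslow_partial_loglik(
    beta: np.ndarray, X: np.ndarray, times: np.ndarray, events: np.ndarray
) -> float:
    """Cox partial log-likelihood with Breslow tie handling."""
    eta = X @ beta
    order = np.argsort(-times, kind="stable")  # decreasing time
    eta_o, t_o, e_o = eta[order], times[order], events[order]
    log_risk = np.logaddexp.accumulate(eta_o)
    ll = 0.0
    i = 0
    n = len(t_o)
    while i < n:
        j = i
        while j + 1 < n and t_o[j + 1] == t_o[i]:
            j += 1
        denom = log_risk[j]  # everyone with time >= t_o[i]
        for k in range(i, j + 1):
            if e_o[k]:
                ll += eta_o[k] - denom
        i = j + 1
    return float(ll)


def fit_lasso_cox(
    expr: pd.DataFrame,
    times: Sequence[float],
    events: Sequence[int],
    lambda_strategy: str = "cv_min",
    folds: int = 10,
    seed: int = 0,
) -> tuple[dict[str, float], float]:
    """Select genes by an L1-penalized Cox fit along a penalty path.

    ``expr`` is genes x samples.  Returns the nonzero coefficients and
    the penalty used.  ``lambda_strategy='cv_min'`` picks the penalty
    minimizing the cross-validated partial-likelihood deviance;
    ``'max'`` returns the sparsest end of the path (used as a fallback
    when the fit degenerates).
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    if (times <= 0).any():
        raise ValueError("survival times must be positive")
    X = expr.to_numpy(dtype=float).T  # samples x genes
    y = Surv.from_arrays(event=events.astype(bool), time=times)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        path_model = CoxnetSurvivalAnalysis(l1_ratio=1.0, alpha_min_ratio=0.01)
        try:
            path_model.fit(X, y)
        except (ArithmeticError, ValueError) as exc:
            logger.warning("penalty path failed (%s); returning empty selection", exc)
            return {}, float("inf")
    alphas = np.asarray(path_model.alphas_)

    if lambda_strategy == "max":
        best_alpha = float(alphas[0])
    elif lambda_strategy == "cv_min":
        best_alpha = _cv_select_alpha(X, y, times, events, alphas, folds, seed)
    else:
        raise ValueError(f"unknown lambda_strategy {lambda_strategy!r}")

    ai = int(np.argmin(np.abs(alphas - best_alpha)))
    coefs = np.asarray(path_model.coef_)[:, ai]
    selected = {
        g: float(c) for g, c in zip(expr.index, coefs) if c != 0.0
    }
    return selected, best_alpha


def _cv_select_alpha(
    X: np.ndarray,
    y: np.ndarray,
    times: np.ndarray,
    events: np.ndarray,
    alphas: np.ndarray,
    folds: int,
    seed: int,
) -> float:
    """Cross-validated partial-likelihood deviance, minimized over the path.

    Per fold f and penalty a: dev = -2 * [ loglik(all data; beta) -
    loglik(train fold; beta) ], the held-out contribution of the fold.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    n = X.shape[0]
    folds = max(2, min(folds, int(events.sum())))
    # stratify folds by event status so every training set has events
    idx_event = rng.permutation(np.flatnonzero(events == 1))
    idx_censor = rng.permutation(np.flatnonzero(events == 0))
    fold_of = np.empty(n, dtype=int)
    fold_of[idx_event] = np.arange(len(idx_event)) % folds
    fold_of[idx_censor] = np.arange(len(idx_censor)) % folds

    dev = np.zeros((folds, len(alphas)))
    valid = np.ones(len(alphas), dtype=bool)
    for f in range(folds):
        train = fold_of != f
        if events[train].sum() < 2:
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=list(alphas))
            try:
                m.fit(X[train], y[train])
            except (ArithmeticError, ValueError):
                continue
        fitted = np.asarray(m.alphas_)
        for ai, a in enumerate(alphas):
            ji = int(np.argmin(np.abs(fitted - a)))
            if not np.isclose(fitted[ji], a, rtol=1e-5):
                valid[ai] = False
                continue
            beta = m.coef_[:, ji]
            ll_all = _breslow_partial_loglik(beta, X, times, events)
            ll_train = _breslow_partial_loglik(
                beta, X[train], times[train], events[train]
            )
            dev[f, ai] += -2.0 * (ll_all - ll_train)
    mean_dev = dev.sum(axis=0)
    mean_dev[~valid] = np.inf
    return float(alphas[int(np.argmin(mean_dev))])


def risk_scores(
    expr: pd.DataFrame, coefficients: Mapping[str, float]
) -> tuple[pd.Series, float, pd.Series]:
    """Per-patient risk scores and the median split.

    score_s = sum_g coef_g * expr[g, s]; group 1 iff score strictly
    above the median (ties go to the low group).
    """
    missing = [g for g in coefficients if g not in expr.index]
    if missing:
        raise KeyError(f"coefficient genes absent from expression: {missing[:5]}")
    scores = pd.Series(0.0, index=expr.columns)
    for g, c in coefficients.items():
        scores = scores + c * expr.loc[g]
    median = float(np.median(scores.to_numpy())) if len(scores) else 0.0
    group = (scores > median).astype(int)
    return scores, median, group


def kaplan_meier(times: Sequence[float], events: Sequence[int]) -> pd.DataFrame:
    """Product-limit survival curve: columns ``time`` and ``survival``.

    Starts at S(0) = 1 and multiplies (1 - d_i/n_i) across event times.
    """
    times = np.asarray(list(times), dtype=float)
    events = np.asarray(list(events), dtype=int)
    if (times < 0).any():
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    sf = kmf.survival_function_
    return pd.DataFrame({"time": sf.index.to_numpy(dtype=float), "survival": sf.iloc[:, 0].to_numpy()})


def logrank(
    times_a: Sequence[float],
    events_a: Sequence[int],
    times_b: Sequence[float],
    events_b: Sequence[int],
) -> tuple[float, float]:
    """Two-group log-rank chi-square statistic (1 df) and p-value."""
    if len(list(times_a)) == 0 or len(list(times_b)) == 0:
        raise ValueError("both groups must be non-empty")
    res = logrank_test(times_a, times_b, event_observed_A=events_a, event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def run_survival_analysis(
    expr: pd.DataFrame,
    survival: pd.DataFrame,
    folds: int = 10,
    seed: int = 0,
) -> SurvivalResult:
    """End-to-end: lasso-Cox selection, median risk split, KM + log-rank.

    ``survival`` needs columns sample_id, os_days, os_event and must
    cover the expression columns.
    """
    surv = survival.set_index("sample_id").loc[list(expr.columns)]
    times = surv["os_days"].to_numpy(dtype=float)
    events = surv["os_event"].to_numpy(dtype=int)
    selected, lam = fit_lasso_cox(expr, times, events, folds=folds, seed=seed)
    scores, median, group = risk_scores(expr, selected)
    km_curves: dict[int, pd.DataFrame] = {}
    for g in (0, 1):
        mask = (group == g).to_numpy()
        if mask.any():
            km_curves[g] = kaplan_meier(times[mask], events[mask])
    if (group == 0).any() and (group == 1).any():
        stat, p = logrank(
            times[(group == 0).to_numpy()],
            events[(group == 0).to_numpy()],
            times[(group == 1).to_numpy()],
            events[(group == 1).to_numpy()],
        )
    else:
        stat, p = 0.0, 1.0
    return SurvivalResult(
        selected_genes=selected,
        risk_score=scores,
        median_risk=median,
        group=group,
        km_curves=km_curves,
        logrank_statistic=stat,
        logrank_p=p,
        lambda_=lam,
        seed=seed,
    )
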