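"""Prediction-accuracy metrics and strategy comparisons.

MSE is the mean squared residual over an evaluation set; NRMSE is the root
MSE divided by the magnitude of the mean observed value in the same scope
(per environment, or pooled across environments for the "Global" scope).
The relative efficiency RE(A/B) = metric_A / metric_B compares two tuning
strategies: RE > 1 means the denominator strategy predicted better.

Aggregation is fold-first: each metric is computed per outer fold, then
averaged, with the fold-to-fold standard error reported alongside. Relative
efficiencies are ratios of the scope-level mean metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "mse",
    "nrmse",
    "relative_efficiency",
    "summarize",
    "EvaluationReport",
    "GLOBAL_SCOPE",
    "COMPARISONS",
]

GLOBAL_SCOPE = "Global"
#: Strategy pairs compared, as (numerator, denominator).
COMPARISONS = (("NT", "BO"), ("NT", "GrS"), ("GrS", "BO"))


def mse(y_obs, y_hat) -> float:
    """Mean squared error."""
    y = np.asarray(y_obs, dtype=float)
    f = np.asarray(y_hat, dtype=float)
    if y.size == 0:
        raise ValueError("mse of an empty set is undefined")
    if y.shape != f.shape:
        raise ValueError(f"length mismatch: {y.shape} observed vs {f.shape} predicted")
    return float(np.mean((y - f) ** 2))


def nrmse(y_obs, y_hat) -> float:
    """Normalized RMSE: sqrt(MSE) / |mean(y_obs)| over the evaluation scope."""
    y = np.asarray(y_obs, dtype=float)
    ybar = float(np.mean(y))
    if abs(ybar) < 1e-12:
        raise ValueError(
            "NRMSE normalization failed: mean of observed values is zero"
        )
    return float(np.sqrt(mse(y_obs, y_hat)) / abs(ybar))


def relative_efficiency(metric_numerator: float, metric_denominator: float) -> float:
    """Plain ratio of two error metrics; > 1 favors the denominator strategy."""
    if metric_denominator <= 0:
        raise ValueError("relative efficiency undefined for non-positive denominator")
    return float(metric_numerator) / float(metric_denominator)


@dataclass
class EvaluationReport:
    """Per-scope metrics and pairwise relative efficiencies.

    ``metrics`` has one row per scope x strategy with columns
    (scope, strategy, mse, se_mse, nrmse, se_nrmse); ``relative_efficiencies``
    one row per comparison x scope with columns
    (comparison, scope, re_mse, re_nrmse).
    """

    metrics: pd.DataFrame
    relative_efficiencies: pd.DataFrame
    n_folds: int
    fold_results: list = field(default_factory=list, repr=False)


def summarize(fold_results, scopes=None) -> EvaluationReport:
    """Aggregate per-fold predictions into an evaluation report.

    ``fold_results`` is an iterable of objects with attributes ``strategy``,
    ``fold_index`` and ``predictions`` (a frame with columns line, env,
    y_obs, y_hat). Metrics are computed per fold within each scope (each
    environment, plus pooled "Global"), then averaged over folds with
    SE = sd / sqrt(n_folds).
    """
    fold_results = list(fold_results)
    if not fold_results:
        raise ValueError("no fold results to summarize")
    strategies = sorted({fr.strategy for fr in fold_results},
                        key=lambda s: ("NT", "GrS", "BO").index(s) if s in ("NT", "GrS", "BO") else 99)
    all_pred = pd.concat(
        [fr.predictions.assign(strategy=fr.strategy, fold=fr.fold_index)
         for fr in fold_results],
        ignore_index=True,
    )
    envs = sorted(all_pred["env"].astype(str).unique())
    if scopes is None:
        scopes = envs + [GLOBAL_SCOPE]
    rows = []
    for strategy in strategies:
        sub = all_pred[all_pred["strategy"] == strategy]
        folds = sorted(sub["fold"].unique())
        if len(folds) < 2:
            raise ValueError("summarize needs at least 2 folds")
        for scope in scopes:
            fold_mse, fold_nrmse = [], []
            for f in folds:
                sf = sub[sub["fold"] == f]
                if scope != GLOBAL_SCOPE:
                    sf = sf[sf["env"].astype(str) == scope]
                if len(sf) == 0:
                    raise ValueError(
                        f"scope {scope!r} has no predictions in fold {f}"
                    )
                fold_mse.append(mse(sf["y_obs"], sf["y_hat"]))
                fold_nrmse.append(nrmse(sf["y_obs"], sf["y_hat"]))
            k = len(folds)
            rows.append({
                "scope": scope,
                "strategy": strategy,
                "mse": float(np.mean(fold_mse)),
                "se_mse": float(np.std(fold_mse, ddof=1) / np.sqrt(k)),
                "nrmse": float(np.mean(fold_nrmse)),
                "se_nrmse": float(np.std(fold_nrmse, ddof=1) / np.sqrt(k)),
            })
    metrics = pd.DataFrame(rows)
    re_rows = []
    for num, den in COMPARISONS:
        if num not in strategies or den not in strategies:
            continue
        for scope in scopes:
            m_num = metrics[(metrics.strategy == num) & (metrics.scope == scope)].iloc[0]
            m_den = metrics[(metrics.strategy == den) & (metrics.scope == scope)].iloc[0]
            re_rows.append({
                "comparison": f"{num}/{den}",
                "scope": scope,
                "re_mse": relative_efficiency(m_num["mse"], m_den["mse"]),
                "re_nrmse": relative_efficiency(m_num["nrmse"], m_den["nrmse"]),
            })
    n_folds = len({fr.fold_index for fr in fold_results})
    return EvaluationReport(
        metrics=metrics,
        relative_efficiencies=pd.DataFrame(re_rows),
        n_folds=n_folds,
        fold_results=fold_results,
    )
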