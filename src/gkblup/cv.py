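"""Nested cross-validation over lines: 7 outer folds, 5 inner folds.

Folds are assigned at the line level so a genotype never appears in both
training and testing, and are stratified by environment when lines are
nested within environments so every training set can estimate every
environment effect. For each outer fold the chosen strategy tunes the
bandwidth on the inner folds of the outer-training set, the model is refit
on the full outer-training set at the selected bandwidth, and the
outer-testing records are predicted. All strategies share the fold plan and
the per-fold model seeds, so comparisons are paired.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .gblup import ModelSpec, fit_gibbs, predict
from .kernels import MarkerMatrix, squared_distance_matrix
from .metrics import EvaluationReport, summarize
from .tuning import (
    InnerCVObjective,
    KernelCache,
    TuningResult,
    bayes_opt,
    grid_search,
    no_tuning,
)
from .utils import seed_for

__all__ = [
    "FoldPlan",
    "FoldResult",
    "make_fold_plan",
    "run_strategy",
    "run_experiment",
    "STRATEGIES",
]

STRATEGIES = ("NT", "GrS", "BO")
N_OUTER = 7
N_INNER = 5


@dataclass(frozen=True)
class FoldPlan:
    """Line-level fold assignments: outer 1-of-7 and, per outer fold, inner
    1-of-5 over the outer-training lines."""

    outer: dict
    inner: dict
    seed: int

    def outer_fold_lines(self, fold: int):
        return [l for l, f in self.outer.items() if f == fold]


@dataclass
class FoldResult:
    """Predictions and tuning outcome for one outer fold of one strategy."""

    fold_index: int
    strategy: str
    selected_rho: float
    predictions: pd.DataFrame  # columns: line, env, y_obs, y_hat
    tuning: TuningResult


def _stratified_assign(lines_by_stratum, n_folds, rng):
    """Cyclic assignment over shuffled strata: globally balanced (sizes differ
    by at most 1) and near-balanced within each stratum."""
    ordered = []
    for stratum in lines_by_stratum:
        stratum = list(stratum)
        rng.shuffle(stratum)
        ordered.extend(stratum)
    return {line: i % n_folds for i, line in enumerate(ordered)}


def make_fold_plan(phenotypes: pd.DataFrame, seed: int,
                   n_outer: int = N_OUTER, n_inner: int = N_INNER) -> FoldPlan:
    """Deterministic line-level fold plan.

    Lines appearing in a single environment are stratified by that
    environment; lines crossed with several environments form one stratum.
    """
    ph = phenotypes.copy()
    ph["line"] = ph["line"].astype(str)
    ph["env"] = ph["env"].astype(str)
    lines = sorted(ph["line"].unique())
    if len(lines) < 2 * n_outer:
        raise ValueError(
            f"need at least {2 * n_outer} distinct lines for {n_outer} outer "
            f"folds, got {len(lines)}"
        )
    env_of = ph.groupby("line")["env"].agg(lambda s: tuple(sorted(set(s))))
    nested = env_of.map(len).eq(1).all()

    def strata(candidates):
        if nested:
            groups = {}
            for l in candidates:
                groups.setdefault(env_of[l], []).append(l)
            return [groups[k] for k in sorted(groups)]
        return [list(candidates)]

    rng = np.random.default_rng(seed_for(seed, "outer"))
    outer = _stratified_assign(strata(lines), n_outer, rng)
    inner = {}
    for f in range(n_outer):
        train_lines = [l for l in lines if outer[l] != f]
        rng_f = np.random.default_rng(seed_for(seed, "inner", f))
        inner[f] = _stratified_assign(strata(train_lines), n_inner, rng_f)
    return FoldPlan(outer=outer, inner=inner, seed=int(seed))


def _tune(strategy, objective, base_seed, fold, grid, bo_budget):
    if strategy == "NT":
        return no_tuning()
    if strategy == "GrS":
        return grid_search(objective, grid=grid)
    if strategy == "BO":
        return bayes_opt(objective, budget=bo_budget,
                         seed=seed_for(base_seed, "bo", fold))
    raise ValueError(f"unknown strategy {strategy!r}; expected one of {STRATEGIES}")


def run_strategy(
    markers: MarkerMatrix,
    phenotypes: pd.DataFrame,
    strategy: str,
    fold_plan: FoldPlan,
    spec: ModelSpec,
    grid=None,
    bo_budget: int = 22,
    kernels: KernelCache | None = None,
):
    """Nested CV for one tuning strategy; returns a list of 7 FoldResults."""
    ph = phenotypes.reset_index(drop=True).copy()
    ph["line"] = ph["line"].astype(str)
    ph["env"] = ph["env"].astype(str)
    if kernels is None:
        kernels = KernelCache(squared_distance_matrix(markers))
    n_outer = max(fold_plan.outer.values()) + 1
    results = []
    seen = 0
    for f in range(n_outer):
        test_lines = set(fold_plan.outer_fold_lines(f))
        is_test = ph["line"].isin(test_lines)
        train_ph = ph.loc[~is_test]
        test_ph = ph.loc[is_test]
        missing_envs = set(test_ph["env"]) - set(train_ph["env"])
        if missing_envs:
            raise ValueError(
                f"outer fold {f}: training set lacks environment "
                f"{sorted(missing_envs)[0]!r} present in its test set"
            )
        if strategy == "NT":
            tuning = no_tuning()
        else:
            objective = InnerCVObjective(
                phenotypes=train_ph,
                kernels=kernels,
                inner_folds=fold_plan.inner[f],
                model_spec=spec,
                seed_tags=("outer", f),
            )
            tuning = _tune(strategy, objective, spec.seed, f, grid, bo_budget)
        K = kernels.get(tuning.selected_rho)
        refit_spec = replace(spec, seed=seed_for(spec.seed, "refit", f))
        fit = fit_gibbs(train_ph, K, refit_spec)
        pred = predict(fit, K, test_ph[["line", "env"]])
        predictions = pd.DataFrame({
            "line": test_ph["line"].to_numpy(),
            "env": test_ph["env"].to_numpy(),
            "y_obs": test_ph["value"].to_numpy(dtype=float),
            "y_hat": pred["y_hat"].to_numpy(),
        })
        seen += len(predictions)
        results.append(FoldResult(
            fold_index=f,
            strategy=strategy,
            selected_rho=tuning.selected_rho,
            predictions=predictions,
            tuning=tuning,
        ))
    if seen != len(ph):
        raise AssertionError("outer folds did not cover every record exactly once")
    return results


def run_experiment(
    markers: MarkerMatrix,
    phenotypes: pd.DataFrame,
    spec: ModelSpec,
    seed: int | None = None,
    strategies=STRATEGIES,
    grid=None,
    bo_budget: int = 22,
) -> EvaluationReport:
    """Run all strategies on one shared fold plan and aggregate.

    The fold plan, inner folds, per-fold model seeds and per-rho kernels are
    shared across strategies, so the reported relative efficiencies isolate
    the effect of bandwidth selection.
    """
    seed = spec.seed if seed is None else seed
    spec = replace(spec, seed=int(seed))
    fold_plan = make_fold_plan(phenotypes, seed=seed)
    kernels = KernelCache(squared_distance_matrix(markers))
    all_results = []
    for strategy in strategies:
        all_results.extend(run_strategy(
            markers, phenotypes, strategy, fold_plan, spec,
            grid=grid, bo_budget=bo_budget, kernels=kernels,
        ))
    report = summarize(all_results)
    return report
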