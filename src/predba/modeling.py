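"""Feature selection, the two-layer stacking ensemble, and LOOCV evaluation.

The regression target is the dissociation free energy ΔG.  For each complex
class, features are ranked by the absolute Pearson correlation with ΔG and a
greedy forward search picks at most five of the top ten.  The predictor is a
two-layer stack: gradient-boosted trees, AdaBoost trees and bagged trees on
the first layer, whose predictions feed an XGBoost meta-regressor.

Meta-training defaults to out-of-fold base predictions (mode="oof"); the
naive variant in which base models predict their own training data
(mode="paper_naive") is kept for comparison but leaks badly at small n.

The greedy search needs a generalization estimate that is cheap enough to
evaluate hundreds of times inside leave-one-out loops; the default objective
is the closed-form leave-one-out Pearson correlation of a ridge regressor
(hat-matrix identity), with a cross-validated stack objective available as
an opt-in for small pools.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostRegressor,
    BaggingRegressor,
    GradientBoostingRegressor,
)
from sklearn.model_selection import KFold
from sklearn.tree import DecisionTreeRegressor
from xgboost import XGBRegressor

from .catalogue import CATALOGUE_ORDER, PAPER_FEATURE_SETS

logger = logging.getLogger(__name__)

MODEL_FORMAT_VERSION = 1
_SEED_MOD = 2**31 - 19


# ---------------------------------------------------------------------------
# Metrics (implemented from their definitions; scipy/sklearn serve only as
# independent oracles in the test suite).


def pearson_r(a: Sequence[float], b: Sequence[float]) -> float:
    """Pearson correlation coefficient between two equal-length vectors."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("pearson_r: need two equal-length 1-d vectors")
    if len(a) < 3:
        raise ValueError("pearson_r: need at least 3 samples")
    da = a - a.mean()
    db = b - b.mean()
    denom = np.sqrt((da * da).sum()) * np.sqrt((db * db).sum())
    if denom == 0.0:
        raise ValueError("pearson_r: zero variance input")
    return float((da * db).sum() / denom)


def mae(a: Sequence[float], b: Sequence[float]) -> float:
    """Mean absolute error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("mae: length mismatch")
    return float(np.abs(a - b).mean())


def r2(actual: Sequence[float], predicted: Sequence[float]) -> float:
    """Coefficient of determination, 1 - SS_res / SS_tot."""
    a = np.asarray(actual, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if a.shape != p.shape:
        raise ValueError("r2: length mismatch")
    ss_tot = ((a - a.mean()) ** 2).sum()
    if ss_tot == 0.0:
        raise ValueError("r2: zero variance in actual values")
    return float(1.0 - ((a - p) ** 2).sum() / ss_tot)


# ---------------------------------------------------------------------------
# Feature ranking and greedy forward selection.


def rank_features(
    table: pd.DataFrame, y: np.ndarray, top: int = 10
) -> list[tuple[str, float]]:
    """Top features by |Pearson r| with the target, descending.

    Features with any missing value or zero variance are excluded; ties are
    broken by catalogue order (then name), so the ranking is deterministic.
    """
    y = np.asarray(y, dtype=float)
    if len(table) < 3:
        raise ValueError("rank_features: need at least 3 rows")
    scored = []
    for name in table.columns:
        col = table[name].to_numpy(dtype=float)
        if np.isnan(col).any():
            continue
        try:
            score = abs(pearson_r(col, y))
        except ValueError:
            continue  # zero variance
        scored.append((name, score))
    scored.sort(
        key=lambda t: (-t[1], CATALOGUE_ORDER.get(t[0], len(CATALOGUE_ORDER)), t[0])
    )
    return scored[:top]


def ridge_loo_pearson(X: np.ndarray, y: np.ndarray, alpha: float = 1e-6) -> float:
    """Leave-one-out Pearson r of a ridge fit, via the hat-matrix identity.

    Columns are standardized; the intercept is unpenalized.  Raises on
    degenerate designs (leverage ~ 1 or zero-variance predictions).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0.0):
        raise ValueError("constant feature in design")
    Xs = (X - mu) / sd
    A = np.column_stack([np.ones(len(y)), Xs])
    penalty = alpha * np.eye(A.shape[1])
    penalty[0, 0] = 0.0
    G = A.T @ A + penalty
    Ginv = np.linalg.inv(G)
    beta = Ginv @ (A.T @ y)
    h = np.einsum("ij,jk,ik->i", A, Ginv, A)
    denom = 1.0 - h
    if np.any(denom < 1e-8):
        raise ValueError("leverage ~ 1: LOO residuals undefined")
    loo_pred = y - (y - A @ beta) / denom
    return pearson_r(y, loo_pred)


Objective = Callable[[np.ndarray, np.ndarray], float]


@dataclass
class SelectionResult:
    ranked: list[tuple[str, float]]
    selected: list[str]
    objective_trace: list[float]


def greedy_select(
    table: pd.DataFrame,
    y: np.ndarray,
    pool: Sequence[str] | None = None,
    objective: Objective | None = None,
    max_k: int = 5,
    epsilon: float = 1e-4,
    top: int = 10,
) -> SelectionResult:
    """Greedy forward selection over the ranked pool.

    At each step the candidate maximizing the objective is added; the search
    stops when the best improvement is ≤ ``epsilon`` or ``max_k`` features
    are selected.  Candidate ties are broken by pool (ranked) order; failing
    candidates (degenerate designs) are skipped with a warning.  The
    objective trace is strictly increasing by construction.
    """
    y = np.asarray(y, dtype=float)
    ranked = rank_features(table, y, top=top)
    if pool is None:
        pool_names = [name for name, _ in ranked]
    else:
        pool_names = list(pool)
    if not pool_names:
        raise ValueError("greedy_select: empty feature pool")
    if objective is None:
        objective = ridge_loo_pearson

    selected: list[str] = []
    trace: list[float] = []
    best_so_far = -np.inf
    while len(selected) < max_k:
        best_name = None
        best_val = -np.inf
        for name in pool_names:
            if name in selected:
                continue
            cols = table[selected + [name]].to_numpy(dtype=float)
            try:
                val = objective(cols, y)
            except (ValueError, np.linalg.LinAlgError) as exc:
                logger.warning("candidate %s skipped: %s", name, exc)
                continue
            if val > best_val:
                best_val = val
                best_name = name
        if best_name is None:
            break
        improvement = best_val - best_so_far
        if selected and improvement <= epsilon:
            break
        selected.append(best_name)
        trace.append(best_val)
        best_so_far = best_val
    return SelectionResult(ranked=ranked, selected=selected, objective_trace=trace)


def make_stack_cv_objective(
    params: "StackParams | None" = None, seed: int = 0, n_splits: int = 3
) -> Objective:
    """Opt-in greedy objective: out-of-fold Pearson r of the full stack.

    Orders of magnitude slower than the default ridge objective; intended
    for small pools and small n.
    """
    params = params or StackParams()

    def objective(X: np.ndarray, y: np.ndarray) -> float:
        k = min(n_splits, len(y) - 1)
        if k < 2:
            raise ValueError("too few rows for a CV objective")
        oof = np.empty(len(y))
        kf = KFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
        for train, test in kf.split(X):
            model = fit_stack(
                X[train], y[train], seed=seed, mode="paper_naive", params=params
            )
            oof[test] = model.predict(X[test])
        return pearson_r(y, oof)

    return objective


# ---------------------------------------------------------------------------
# The two-layer stack.


@dataclass(frozen=True)
class StackParams:
    """Hyperparameters of the two-layer stack (all config-exposed)."""

    gbrt_n_estimators: int = 100
    gbrt_max_depth: int = 3
    gbrt_learning_rate: float = 0.1
    ada_n_estimators: int = 50
    ada_max_depth: int = 3
    bag_n_estimators: int = 50
    meta_n_estimators: int = 100
    meta_max_depth: int = 2
    meta_learning_rate: float = 0.1
    meta_reg_lambda: float = 1.0
    n_folds: int = 5


BASE_MODEL_NAMES = ("GBRT", "AdaR", "BagR")


def _make_base_models(params: StackParams, seed: int) -> dict:
    s = seed % _SEED_MOD
    return {
        "GBRT": GradientBoostingRegressor(
            n_estimators=params.gbrt_n_estimators,
            max_depth=params.gbrt_max_depth,
            learning_rate=params.gbrt_learning_rate,
            random_state=s,
        ),
        "AdaR": AdaBoostRegressor(
            DecisionTreeRegressor(max_depth=params.ada_max_depth),
            n_estimators=params.ada_n_estimators,
            random_state=(s + 1) % _SEED_MOD,
        ),
        "BagR": BaggingRegressor(
            DecisionTreeRegressor(),
            n_estimators=params.bag_n_estimators,
            random_state=(s + 2) % _SEED_MOD,
        ),
    }


def _make_meta_model(params: StackParams, seed: int) -> XGBRegressor:
    return XGBRegressor(
        n_estimators=params.meta_n_estimators,
        max_depth=params.meta_max_depth,
        learning_rate=params.meta_learning_rate,
        reg_lambda=params.meta_reg_lambda,
        random_state=(seed + 3) % _SEED_MOD,
        n_jobs=1,
    )


@dataclass
class StackModel:
    base_models: dict
    meta_model: XGBRegressor
    selected_features: list[str] | None
    seed: int
    mode: str
    params: StackParams
    oof_folds: int | None = None

    def _matrix(self, features) -> np.ndarray:
        if isinstance(features, pd.DataFrame):
            if self.selected_features is not None:
                missing = [
                    f for f in self.selected_features if f not in features.columns
                ]
                if missing:
                    raise KeyError(f"missing selected feature columns: {missing}")
                features = features[self.selected_features]
            return features.to_numpy(dtype=float)
        return np.asarray(features, dtype=float)

    def predict(self, features) -> np.ndarray:
        """Meta-model output on the three base-model predictions."""
        X = self._matrix(features)
        Z = np.column_stack(
            [self.base_models[name].predict(X) for name in BASE_MODEL_NAMES]
        )
        return np.asarray(self.meta_model.predict(Z), dtype=float)


def fit_stack(
    table,
    y: np.ndarray,
    selected: Sequence[str] | None = None,
    seed: int = 0,
    mode: str = "oof",
    params: StackParams | None = None,
) -> StackModel:
    """Fit the two-layer stack.

    mode="oof": base predictions used to train the meta-model come from
    K = min(n_folds, n-1) out-of-fold splits; the base models are then refit
    on all rows.  mode="paper_naive": base models fit on all rows and predict
    those same rows to form the meta-training matrix (the literal two-layer
    recipe; leaks at small n).
    """
    params = params or StackParams()
    y = np.asarray(y, dtype=float)
    if isinstance(table, pd.DataFrame):
        sel = list(selected) if selected is not None else list(table.columns)
        missing = [f for f in sel if f not in table.columns]
        if missing:
            raise KeyError(f"missing selected feature columns: {missing}")
        X = table[sel].to_numpy(dtype=float)
    else:
        X = np.asarray(table, dtype=float)
        sel = list(selected) if selected is not None else None
    n = len(y)
    if n < 5:
        raise ValueError(
            "fit_stack: need at least 5 samples (use a single base learner "
            "for smaller data)"
        )
    if mode not in ("oof", "paper_naive"):
        raise ValueError(f"unknown stacking mode {mode!r}")

    base = _make_base_models(params, seed)
    meta = _make_meta_model(params, seed)
    oof_folds = None
    if mode == "oof":
        k = min(params.n_folds, n - 1)
        oof_folds = k
        Z = np.empty((n, len(BASE_MODEL_NAMES)))
        kf = KFold(n_splits=k, shuffle=True, random_state=seed % _SEED_MOD)
        for train, test in kf.split(X):
            fold_models = _make_base_models(params, seed)
            for col, name in enumerate(BASE_MODEL_NAMES):
                fold_models[name].fit(X[train], y[train])
                Z[test, col] = fold_models[name].predict(X[test])
        for name in BASE_MODEL_NAMES:
            base[name].fit(X, y)
    else:
        for name in BASE_MODEL_NAMES:
            base[name].fit(X, y)
        Z = np.column_stack([base[name].predict(X) for name in BASE_MODEL_NAMES])
    meta.fit(Z, y)
    return StackModel(
        base_models=base,
        meta_model=meta,
        selected_features=sel if isinstance(table, pd.DataFrame) else sel,
        seed=seed,
        mode=mode,
        params=params,
        oof_folds=oof_folds,
    )


def save_model(model: StackModel, path) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "seed": model.seed,
            "mode": model.mode,
            "params": asdict(model.params),
            "selected_features": model.selected_features,
            "oof_folds": model.oof_folds,
            "base_models": model.base_models,
            "meta_model": model.meta_model,
        },
        path,
    )


def load_model(path) -> StackModel:
    blob = joblib.load(path)
    version = blob.get("format_version")
    if version != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format version {version!r}")
    return StackModel(
        base_models=blob["base_models"],
        meta_model=blob["meta_model"],
        selected_features=blob["selected_features"],
        seed=blob["seed"],
        mode=blob["mode"],
        params=StackParams(**blob["params"]),
        oof_folds=blob["oof_folds"],
    )


# ---------------------------------------------------------------------------
# Leave-one-out evaluation.


@dataclass
class EvalReport:
    class_label: str | None
    mode: str
    seed: int
    n: int
    r: float
    mae: float
    r2: float
    pairs: list[tuple[str, float, float]]  # (complex_id, actual, predicted)
    selections: list[list[str]] = field(default_factory=list)

    def to_json(self) -> str:
        payload = {
            "class_label": self.class_label,
            "mode": self.mode,
            "seed": self.seed,
            "n": self.n,
            "r": self.r,
            "mae": self.mae,
            "r2": self.r2,
            "pairs": [list(p) for p in self.pairs],
            "selections": self.selections,
        }
        return json.dumps(payload, sort_keys=True, indent=2)


def loocv_evaluate(
    table: pd.DataFrame,
    y: np.ndarray,
    mode: str = "honest",
    selected: Sequence[str] | None = None,
    class_label: str | None = None,
    seed: int = 0,
    params: StackParams | None = None,
    stack_mode: str = "oof",
    max_k: int = 5,
    epsilon: float = 1e-4,
    top: int = 10,
    objective: Objective | None = None,
) -> EvalReport:
    """Leave-one-out evaluation of the full pipeline.

    mode="honest": for each held-out complex, feature ranking, greedy
    selection and the stack are all refit on the remaining n-1 rows.
    mode="paper": the feature set is fixed (``selected``, or the per-class
    preset for ``class_label``) and only the stack is refit per fold.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 6:
        raise ValueError(
            "loocv_evaluate: need at least 6 rows; merge classes or use "
            "paper mode with fixed features on more data"
        )
    params = params or StackParams()
    if mode not in ("honest", "paper"):
        raise ValueError(f"unknown evaluation mode {mode!r}")
    if mode == "paper":
        if selected is None:
            if class_label is None or class_label not in PAPER_FEATURE_SETS:
                raise ValueError(
                    "paper mode needs an explicit feature set or a known "
                    "class label"
                )
            selected = PAPER_FEATURE_SETS[class_label]
        selected = list(selected)

    ids = [str(i) for i in table.index]
    preds = np.empty(n)
    selections: list[list[str]] = []
    index = np.arange(n)
    for i in range(n):
        rest = index[index != i]
        X_train = table.iloc[rest]
        y_train = y[rest]
        if mode == "honest":
            sel_result = greedy_select(
                X_train, y_train, objective=objective,
                max_k=max_k, epsilon=epsilon, top=top,
            )
            sel = sel_result.selected
            if not sel:  # degenerate pool: fall back to the top-ranked feature
                sel = [sel_result.ranked[0][0]]
        else:
            sel = selected
        selections.append(list(sel))
        model = fit_stack(
            X_train, y_train, selected=sel, seed=seed, mode=stack_mode, params=params
        )
        preds[i] = model.predict(table.iloc[[i]])[0]

    return EvalReport(
        class_label=class_label,
        mode=mode,
        seed=seed,
        n=n,
        r=pearson_r(y, preds),
        mae=mae(y, preds),
        r2=r2(y, preds),
        pairs=[(ids[i], float(y[i]), float(preds[i])) for i in range(n)],
        selections=selections,
    )


def evaluate_classes(
    groups: dict[str, tuple[pd.DataFrame, np.ndarray]], **kwargs
) -> dict:
    """Per-class LOOCV reports plus the unweighted average of r/MAE/R²."""
    reports = {}
    for label, (table, y) in groups.items():
        reports[label] = loocv_evaluate(table, y, class_label=label, **kwargs)
    avg = {
        "r": float(np.mean([rep.r for rep in reports.values()])),
        "mae": float(np.mean([rep.mae for rep in reports.values()])),
        "r2": float(np.mean([rep.r2 for rep in reports.values()])),
    }
    return {"per_class": reports, "average": avg}
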