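"""The customTrain/customPredict model contract and learner adapters.

Every model obeys one contract: ``customTrain(model, design, outcome)`` fits
on a samples x features design matrix with a censored outcome, and
``customPredict(model, design)`` returns a finite per-sample score with the
convention *higher = longer predicted survival*.  The learning algorithms
themselves are scikit-survival estimators (they emit risk scores, which the
adapters negate); the contract, seeding, rank transform and the
unpenalized-clinical option are what this module adds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold
from sksurv.ensemble import GradientBoostingSurvivalAnalysis, RandomSurvivalForest
from sksurv.linear_model import CoxnetSurvivalAnalysis, CoxPHSurvivalAnalysis
from sksurv.util import Surv

from .concordance import NoComparablePairsError, concordance_index

logger = logging.getLogger(__name__)

LEARNER_NAMES = [
    "cox_baseline",
    "lasso_cox",
    "elasticnet_cox",
    "boosting",
    "random_survival_forest",
]

DEFAULT_HYPERPARAMS = {
    "cox_baseline": {"alpha": 1e-4},
    "lasso_cox": {"l1_ratio": 1.0, "n_alphas": 30, "cv_folds": 3},
    "elasticnet_cox": {"l1_ratio": 0.5, "n_alphas": 30, "cv_folds": 3},
    "boosting": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "random_survival_forest": {
        "n_estimators": 100, "min_samples_leaf": 10, "max_features": "sqrt",
    },
}


class NotFittedError(RuntimeError):
    pass


@dataclass
class SurvivalModel:
    """A learner adapter holding configuration and, after training, fitted state."""

    name: str
    penalize_clinical: bool = True
    rank_transform: bool = False
    hyperparams: dict = field(default_factory=dict)
    seed: int | None = None
    fitted: bool = False
    _estimator: object = None
    _columns: list = None
    _rank_maps: dict = None
    _sign: float = -1.0  # risk scores are negated to the survival convention


def make_learner(name: str, penalize_clinical: bool = True, rank_transform: bool = False,
                 hyperparams: dict | None = None, seed: int | None = None) -> SurvivalModel:
    """Configure a learner adapter.

    ``penalize_clinical=False`` gives clinical (``clin:``) and aggregate
    (``agg:``) columns zero penalty in penalized Cox fits, so they are always
    retained.  ``rank_transform=True`` replaces each feature by its
    within-training rank; validation values are mapped through interpolated
    training quantiles.
    """
    if name not in LEARNER_NAMES:
        raise ValueError(f"unknown learner {name!r}; known: {LEARNER_NAMES}")
    hp = dict(DEFAULT_HYPERPARAMS[name])
    hp.update(hyperparams or {})
    return SurvivalModel(name=name, penalize_clinical=penalize_clinical,
                         rank_transform=rank_transform, hyperparams=hp, seed=seed)


def _rank_fit(col: np.ndarray):
    """Store the empirical map value -> average rank for one training column."""
    order = np.argsort(col, kind="stable")
    ranks = np.empty(len(col))
    ranks[order] = np.arange(1, len(col) + 1)
    # average ranks over ties
    s = pd.Series(ranks).groupby(pd.Series(col)).transform("mean").to_numpy()
    xs, idx = np.unique(col, return_index=True)
    return xs, s[idx]


def _rank_apply(col: np.ndarray, xs: np.ndarray, rs: np.ndarray) -> np.ndarray:
    return np.interp(col, xs, rs)


def _apply_rank_transform(model: SurvivalModel, X: pd.DataFrame, fit: bool) -> np.ndarray:
    vals = X.to_numpy(float)
    if fit:
        model._rank_maps = {}
        out = np.empty_like(vals)
        for j, c in enumerate(X.columns):
            xs, rs = _rank_fit(vals[:, j])
            model._rank_maps[c] = (xs, rs)
            out[:, j] = _rank_apply(vals[:, j], xs, rs)
        return out
    out = np.empty_like(vals)
    for j, c in enumerate(X.columns):
        xs, rs = model._rank_maps[c]
        out[:, j] = _rank_apply(vals[:, j], xs, rs)
    return out


def _select_coxnet_alpha(X, y, time, event, l1_ratio, penalty_factor, n_alphas, folds, seed):
    """Pick the penalty by internal cross-validated exact concordance."""
    path = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, n_alphas=n_alphas,
                                  penalty_factor=penalty_factor, alpha_min_ratio=0.01)
    path.fit(X, y)
    alphas = path.alphas_
    n = X.shape[0]
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    scores = np.zeros(len(alphas))
    counts = np.zeros(len(alphas))
    for tr, te in kf.split(X):
        try:
            est = CoxnetSurvivalAnalysis(l1_ratio=l1_ratio, alphas=alphas,
                                         penalty_factor=penalty_factor)
            est.fit(X[tr], y[tr])
        except Exception as exc:  # pragma: no cover - degenerate folds
            logger.warning("coxnet CV fold failed: %s", exc)
            continue
        for i, a in enumerate(alphas):
            try:
                risk = est.predict(X[te], alpha=a)
                res = concordance_index(-risk, (time[te], event[te]))
                scores[i] += res.c_index
                counts[i] += 1
            except (NoComparablePairsError, ValueError):
                continue
    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, scores / np.maximum(counts, 1), -np.inf)
    if np.all(~np.isfinite(mean)):
        best = len(alphas) // 2
    else:
        best = int(np.argmax(mean))
    # candidates: CV-best alpha first, then increasingly heavier penalties as
    # numerical fallbacks (alphas_ is sorted descending)
    fallbacks = sorted((a for a in alphas if a > alphas[best]))
    return [float(alphas[best])] + [float(a) for a in fallbacks]


def customTrain(model: SurvivalModel, design: pd.DataFrame, outcome) -> SurvivalModel:
    """Fit the configured algorithm on a design matrix with censored outcome.

    Censoring is handled by each algorithm's native mechanism (partial
    likelihood for the Cox family, survival trees for the forest, boosted
    Cox risk for boosting).  Penalty parameters are chosen by seeded
    internal cross-validation.  Non-convergence raises; it is never silent.
    """
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values; impute upstream")
    time = np.asarray(outcome.time, float)
    event = np.asarray(outcome.event, int)
    if event.sum() < 2:
        raise ValueError("degenerate outcome: fewer than 2 events")
    if len(design) != len(time):
        raise ValueError("design and outcome have different sample counts")
    model._columns = list(design.columns)
    X = (_apply_rank_transform(model, design, fit=True)
         if model.rank_transform else design.to_numpy(float))
    y = Surv.from_arrays(event=event.astype(bool), time=time)
    hp = model.hyperparams
    seed = model.seed if model.seed is not None else 0

    if model.name == "cox_baseline":
        est = CoxPHSurvivalAnalysis(alpha=hp.get("alpha", 1e-4), n_iter=200)
        est.fit(X, y)
    elif model.name in ("lasso_cox", "elasticnet_cox"):
        penalty_factor = None
        unpenalized_all = False
        if not model.penalize_clinical:
            penalty_factor = np.array(
                [0.0 if c.startswith(("clin:", "agg:")) else 1.0 for c in design.columns]
            )
            if penalty_factor.sum() == 0:
                # glmnet rescales penalty factors to sum to n_features, so a
                # uniform tiny factor would not stay tiny; drive the penalty
                # itself to ~0 instead
                logger.info("all columns unpenalized; fitting at a vanishing penalty")
                penalty_factor = None
                unpenalized_all = True
        l1 = hp["l1_ratio"]
        if unpenalized_all:
            candidates = [1e-8]
        elif "alpha" in hp:
            candidates = [float(hp["alpha"])]
        else:
            candidates = _select_coxnet_alpha(X, y, time, event, l1, penalty_factor,
                                              hp.get("n_alphas", 30),
                                              hp.get("cv_folds", 3), seed)
        est = None
        errors = []
        for alpha in candidates:
            try:
                est = CoxnetSurvivalAnalysis(l1_ratio=l1, alphas=[alpha],
                                             penalty_factor=penalty_factor)
                est.fit(X, y)
                break
            except (ArithmeticError, ValueError) as exc:
                errors.append(f"alpha={alpha:g}: {exc}")
                est = None
        if est is None:
            raise RuntimeError(f"{model.name} failed at every penalty: {errors[:3]}")
        if len(errors):
            logger.info("%s fell back to heavier penalty after: %s", model.name, errors[0])
    elif model.name == "boosting":
        est = GradientBoostingSurvivalAnalysis(
            n_estimators=hp["n_estimators"], max_depth=hp["max_depth"],
            learning_rate=hp["learning_rate"], random_state=seed,
        )
        est.fit(X, y)
    elif model.name == "random_survival_forest":
        est = RandomSurvivalForest(
            n_estimators=hp["n_estimators"], min_samples_leaf=hp["min_samples_leaf"],
            max_features=hp["max_features"], random_state=seed, n_jobs=1,
        )
        est.fit(X, y)
    else:  # pragma: no cover - guarded in make_learner
        raise ValueError(model.name)
    model._estimator = est
    model.fitted = True
    return model


def customPredict(model: SurvivalModel, design: pd.DataFrame) -> pd.Series:
    """Predicted-survival scores for the rows of ``design`` (higher = longer).

    Requires a fitted model whose training columns match ``design``'s.
    """
    if not model.fitted:
        raise NotFittedError("customPredict called before customTrain")
    if list(design.columns) != model._columns:
        if set(design.columns) == set(model._columns):
            design = design[model._columns]
        else:
            raise ValueError("design columns do not match training columns")
    if design.isna().any().any():
        raise ValueError("design matrix contains missing values")
    X = (_apply_rank_transform(model, design, fit=False)
         if model.rank_transform else design.to_numpy(float))
    risk = np.asarray(model._estimator.predict(X), dtype=float)
    if not np.all(np.isfinite(risk)):
        raise RuntimeError(f"{model.name} produced non-finite predictions")
    return pd.Series(model._sign * risk, index=design.index, name="predicted_survival")
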