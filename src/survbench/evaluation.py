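"""Controlled-experiment runner and control experiments.

``run_grid`` crosses the feature categories with the base learning
algorithms (default 15 x 4 = 60 models), scores every model on the
validation split with the exact concordance index, and appends the 20
rank-averaging ensembles.  The control experiments quantify what the grid's
scores mean: a label-permutation negative control (scores should collapse to
~0.5), an ER-status positive control (an easy prediction task; scores should
be high), a random-feature null for a candidate model's score, and
cross-cohort consistency of frozen models.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression

from .cohort import Cohort, SurvivalOutcome
from .concordance import concordance_index
from .design import (
    DEFAULT_CATEGORIES,
    CategoryParams,
    FittedCategory,
    encode_clinical,
    fit_category,
    freeze_feature_ids,
    parse_category,
)
from .ensemble import build_ensemble_grid, rank_average_ensemble
from .leaderboard import Leaderboard
from .learners import customPredict, customTrain, make_learner

logger = logging.getLogger(__name__)

DEFAULT_LEARNERS = ["boosting", "random_survival_forest", "lasso_cox", "elasticnet_cox"]


@dataclass
class GridSpec:
    """Feature categories x learners of the controlled experiment."""

    categories: list = field(default_factory=lambda: list(DEFAULT_CATEGORIES))
    learners: list = field(default_factory=lambda: list(DEFAULT_LEARNERS))
    params: CategoryParams = field(default_factory=CategoryParams)
    learner_options: dict = field(default_factory=dict)  # per-learner kwargs
    seed: int = 0

    def validate(self) -> None:
        if not self.categories or len(set(self.categories)) != len(self.categories):
            raise ValueError("categories must be non-empty and unique")
        if not self.learners or len(set(self.learners)) != len(self.learners):
            raise ValueError("learners must be non-empty and unique")


@dataclass
class FittedCell:
    category: str
    learner: str
    assembler: FittedCategory
    model: object
    prediction: pd.Series
    c_index: float


@dataclass
class GridResult:
    leaderboard: Leaderboard
    predictions: dict  # (category, learner) -> validation prediction Series
    cells: dict  # (category, learner) -> FittedCell (successful only)
    ensembles: list  # (EnsembleSpec, Series, c_index)
    spec: GridSpec
    failures: dict = field(default_factory=dict)  # (category, learner) -> message


def _cell_seed(base: int, i: int, j: int) -> int:
    return int(np.random.SeedSequence([base, i, j]).generate_state(1)[0] % (2**31))


def run_grid(cohort: Cohort, spec: GridSpec | None = None) -> GridResult:
    """Train and score every (feature category, learner) cell plus ensembles.

    Any cell failure is recorded as a failed leaderboard row (NaN score) and
    the run continues.  Ensembles are built from each group's successful
    members; a group with no successful member yields a failed ensemble row.
    """
    spec = spec or GridSpec()
    spec.validate()
    cohort.validate()
    train, val = cohort.train_samples, cohort.validation_samples
    out_train = cohort.outcome.loc(train)
    out_val = cohort.outcome.loc(val)
    board = Leaderboard()
    predictions, cells, failures = {}, {}, {}

    for i, category in enumerate(spec.categories):
        params = dc_replace(spec.params, seed=_cell_seed(spec.seed, i, 10_000))
        try:
            assembler = fit_category(cohort, category, params)
            X_train = assembler.transform(cohort, train)
            X_val = assembler.transform(cohort, val)
        except Exception as exc:
            logger.warning("category %s failed: %s", category, exc)
            for j, learner in enumerate(spec.learners):
                failures[(category, learner)] = f"category failed: {exc}"
                board.add(f"{category}|{learner}", category, learner, float("nan"),
                          len(val), provenance=f"failed: {exc}")
            continue
        for j, learner in enumerate(spec.learners):
            model = make_learner(learner, seed=_cell_seed(spec.seed, i, j),
                                 **spec.learner_options.get(learner, {}))
            try:
                customTrain(model, X_train, out_train)
                pred = customPredict(model, X_val)
                res = concordance_index(pred, out_val)
            except Exception as exc:
                logger.warning("cell (%s, %s) failed: %s", category, learner, exc)
                failures[(category, learner)] = str(exc)
                board.add(f"{category}|{learner}", category, learner, float("nan"),
                          len(val), provenance=f"failed: {exc}")
                continue
            predictions[(category, learner)] = pred
            cells[(category, learner)] = FittedCell(category, learner, assembler,
                                                    model, pred, res.c_index)
            board.add(
                f"{category}|{learner}", category, learner, res.c_index, len(val),
                provenance=json.dumps({"n_features": X_train.shape[1],
                                       "seed": model.seed}),
            )

    ensembles = _grid_ensembles(spec, predictions, out_val, board, len(val))
    return GridResult(leaderboard=board, predictions=predictions, cells=cells,
                      ensembles=ensembles, spec=spec, failures=failures)


def _grid_ensembles(spec, predictions, out_val, board, n_val):
    """Per-category, per-learner and grand rank-average ensembles."""
    from .ensemble import EnsembleSpec  # local import to keep dataclass single-sourced

    groups = []
    for c in spec.categories:
        groups.append((f"ensemble_category:{c}", "per_category", c, "ensemble",
                       [(c, l) for l in spec.learners]))
    for l in spec.learners:
        groups.append((f"ensemble_learner:{l}", "per_algorithm", "ensemble", l,
                       [(c, l) for c in spec.categories]))
    groups.append(("ensemble_grand", "grand", "ensemble", "ensemble",
                   [(c, l) for c in spec.categories for l in spec.learners]))
    ensembles = []
    for name, grouping, cat_label, learner_label, members in groups:
        available = [m for m in members if m in predictions]
        if not available:
            board.add(name, cat_label, learner_label, float("nan"), n_val,
                      provenance="failed: no successful members")
            continue
        es = EnsembleSpec(name=name, grouping=grouping, members=tuple(available))
        pred = rank_average_ensemble([predictions[m] for m in available])
        res = concordance_index(pred, out_val)
        ensembles.append((es, pred, res.c_index))
        board.add(name, cat_label, learner_label, res.c_index, n_val,
                  provenance=json.dumps({"members": [f"{c}|{l}" for c, l in available]}))
    return ensembles


# ---------------------------------------------------------------------------
# controls


def negative_control(cohort: Cohort, spec: GridSpec | None = None,
                     seed: int = 0) -> GridResult:
    """Label-permutation negative control.

    Permutes (time, event) jointly across samples, within the training split
    and within the validation split separately, then reruns the grid.  The
    permutation is guaranteed to actually move labels.
    """
    rng = np.random.default_rng(seed)
    time = cohort.outcome.time.copy()
    event = cohort.outcome.event.copy()
    for part in (cohort.train_samples, cohort.validation_samples):
        part = list(part)
        for _ in range(100):
            perm = rng.permutation(len(part))
            if len(part) < 2 or not np.array_equal(perm, np.arange(len(part))):
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw a non-identity permutation")
        time.loc[part] = time.loc[part].to_numpy()[perm]
        event.loc[part] = event.loc[part].to_numpy()[perm]
    permuted = dc_replace(
        cohort, outcome=SurvivalOutcome(time, event), truth=None,
    )
    return run_grid(permuted, spec)


_CLASSIFIER_ANALOGUES = {
    "boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "random_survival_forest": lambda seed: RandomForestClassifier(
        n_estimators=100, random_state=seed),
    "lasso_cox": lambda seed: LogisticRegression(
        l1_ratio=1.0, solver="saga", C=1.0, random_state=seed, max_iter=5000),
    "elasticnet_cox": lambda seed: LogisticRegression(
        l1_ratio=0.5, solver="saga", C=1.0, random_state=seed, max_iter=5000),
}


def positive_control_er(cohort: Cohort, spec: GridSpec | None = None,
                        er_gene: str | None = None) -> Leaderboard:
    """ER-status positive control: an easy prediction task with known signal.

    Each category's *molecular* features (selected on the training split as
    usual) are used to predict the binary ER label with the classification
    analogue of each survival learner; the designated ER expression
    measurement is excluded before selection and its absence from every
    design matrix is asserted.  Scores are the exact concordance of the
    predicted score against the label, which for a binary outcome equals the
    area under the ROC curve.
    """
    spec = spec or GridSpec()
    spec.validate()
    if er_gene is None:
        if not cohort.truth or "er_gene" not in cohort.truth:
            raise ValueError("er_gene must be given for non-synthetic cohorts")
        er_gene = cohort.truth["er_gene"]
    er = cohort.clinical["ER"].astype(int)
    for part in (cohort.train_samples, cohort.validation_samples):
        if er.loc[part].nunique() < 2:
            raise ValueError("single-class ER status in a split")
    stripped = dc_replace(cohort, expression=cohort.expression.drop(index=er_gene))
    train, val = cohort.train_samples, cohort.validation_samples
    label_outcome = SurvivalOutcome(
        pd.Series(er.loc[val] + 1.0, index=val), pd.Series(1, index=val))
    board = Leaderboard()
    for i, category in enumerate(spec.categories):
        strategy, _, _ = parse_category(category)
        if strategy is None:
            logger.info("positive control skips %s (no molecular features)", category)
            continue
        params = dc_replace(spec.params, seed=_cell_seed(spec.seed, i, 20_000))
        assembler = fit_category(stripped, category, params)
        mol_ids = [f for f in assembler.feature_set.ids if f.startswith(("expr:", "cna:"))]
        if f"expr:{er_gene}" in assembler.feature_set.ids:
            raise ValueError("leakage: ER expression measurement present in design")
        custom = freeze_feature_ids(stripped, f"er_control:{category}", mol_ids)
        X_train = custom.transform(stripped, train)
        X_val = custom.transform(stripped, val)
        for j, learner in enumerate(spec.learners):
            clf = _CLASSIFIER_ANALOGUES[learner](_cell_seed(spec.seed, i, 20_000 + j))
            clf.fit(X_train.to_numpy(), er.loc[train].to_numpy())
            score = clf.predict_proba(X_val.to_numpy())[:, 1]
            res = concordance_index(pd.Series(score, index=val), label_outcome)
            board.add(f"er_control:{category}|{learner}", category, learner,
                      res.c_index, len(val), provenance="positive_control")
    if not len(board):
        raise ValueError("no category with molecular features in spec")
    return board


@dataclass
class NullResult:
    """Random-feature null distribution for a candidate model score."""

    scores: np.ndarray
    n_features: int
    learner: str

    def empirical_p(self, candidate: float) -> float:
        """Add-one empirical p-value: (1 + #null >= candidate) / (n + 1)."""
        return (1 + int(np.sum(self.scores >= candidate))) / (len(self.scores) + 1)


def random_feature_null(cohort: Cohort, learner: str, n_models: int = 100,
                        n_features: int = 50, seed: int = 0,
                        clinical_subset: list | None = None) -> NullResult:
    """Null score distribution from clinical + random molecular feature models.

    Fits ``n_models`` models on all clinical covariates plus ``n_features``
    molecular features drawn at random (fresh draw per model), scoring each
    on the validation split.  The candidate's empirical p uses the add-one
    rule so it is never zero.
    """
    cohort.validate()
    pool = [f"expr:{g}" for g in cohort.expression.index] + [
        f"cna:{g}" for g in cohort.cn_genes.index]
    if len(pool) < n_features:
        raise ValueError("fewer molecular features than n_features")
    subset = clinical_subset or list(cohort.clinical.columns)
    clin_cols = list(encode_clinical(cohort.clinical.iloc[:2], subset).columns)
    train, val = cohort.train_samples, cohort.validation_samples
    out_train, out_val = cohort.outcome.loc(train), cohort.outcome.loc(val)
    rng = np.random.default_rng(seed)
    scores = np.empty(n_models)
    for m in range(n_models):
        ids = sorted(rng.choice(pool, size=n_features, replace=False))
        custom = freeze_feature_ids(cohort, f"random_{m}", ids + clin_cols,
                                    clinical_subset=subset)
        model = make_learner(learner, seed=int(rng.integers(2**31)))
        customTrain(model, custom.transform(cohort, train), out_train)
        pred = customPredict(model, custom.transform(cohort, val))
        scores[m] = concordance_index(pred, out_val).c_index
    return NullResult(scores=scores, n_features=n_features, learner=learner)


# ---------------------------------------------------------------------------
# cross-cohort consistency


@dataclass
class ConsistencyResult:
    leaderboards: dict  # cohort name -> Leaderboard
    score_table: pd.DataFrame  # cells x cohorts (including "original")
    correlations: pd.DataFrame  # pairwise Pearson r over model score vectors


def consistency_evaluation(result: GridResult, cohorts: dict,
                           samples: str = "all") -> ConsistencyResult:
    """Re-score the frozen grid models on independent cohorts.

    Models (feature selections and fitted learners) are *not* retrained;
    each cohort must share the original feature namespace.  ``samples`` is
    ``"all"`` (default, score on every sample of the new cohort) or
    ``"validation"``.
    """
    keys = sorted(result.cells)
    table = {"original": pd.Series({f"{c}|{l}": result.cells[(c, l)].c_index
                                    for c, l in keys})}
    boards = {}
    for name, cohort in cohorts.items():
        cohort.validate()
        roster = cohort.samples if samples == "all" else cohort.validation_samples
        out = cohort.outcome.loc(roster)
        board = Leaderboard()
        col = {}
        for c, l in keys:
            cell = result.cells[(c, l)]
            try:
                X = cell.assembler.transform(cohort, roster)
                pred = customPredict(cell.model, X)
                score = concordance_index(pred, out).c_index
            except KeyError as exc:
                raise KeyError(f"feature namespace mismatch on cohort {name!r}: {exc}")
            board.add(f"{c}|{l}", c, l, score, len(roster), provenance=f"rescored:{name}")
            col[f"{c}|{l}"] = score
        boards[name] = board
        table[name] = pd.Series(col)
    score_table = pd.DataFrame(table)
    corr = score_table.corr(method="pearson")
    return ConsistencyResult(leaderboards=boards, score_table=score_table,
                             correlations=corr)


def grid_anova(board: Leaderboard) -> dict:
    """Two-way ANOVA (no interaction) of base-cell scores on category and learner.

    Convenience diagnostic for how much score variance each grid factor
    explains; requires a complete balanced grid of successful base rows.
    """
    df = board.to_frame()
    base = df[(df["feature_category"] != "ensemble") & (df["learner"] != "ensemble")]
    base = base[np.isfinite(base["concordance_index"])]
    cats = base["feature_category"].unique()
    learns = base["learner"].unique()
    if len(base) != len(cats) * len(learns):
        raise ValueError("grid incomplete or unbalanced; ANOVA undefined")
    y = base["concordance_index"].to_numpy()
    grand = y.mean()
    ss_total = np.sum((y - grand) ** 2)
    cat_means = base.groupby("feature_category")["concordance_index"].mean()
    learn_means = base.groupby("learner")["concordance_index"].mean()
    ss_cat = len(learns) * np.sum((cat_means - grand) ** 2)
    ss_learn = len(cats) * np.sum((learn_means - grand) ** 2)
    ss_resid = ss_total - ss_cat - ss_learn
    df_cat, df_learn = len(cats) - 1, len(learns) - 1
    df_resid = (len(cats) - 1) * (len(learns) - 1)
    ms_resid = ss_resid / df_resid
    out = {}
    for factor, ss, dof in [("category", ss_cat, df_cat), ("learner", ss_learn, df_learn)]:
        f = (ss / dof) / ms_resid if ms_resid > 0 else np.inf
        out[factor] = {"F": float(f), "p": float(stats.f.sf(f, dof, df_resid)),
                       "df": (dof, df_resid)}
    return out
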