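"""Rank-averaging ensembles over model predictions.

A consensus prediction is formed by converting each member's predicted
survival vector to within-roster ranks (ascending: higher predicted survival
gets higher rank, ties get the average rank) and averaging the ranks per
sample.  The default ensemble grid builds one ensemble per feature category
(across learners), one per learner (across categories), and one grand
ensemble of every cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = ["EnsembleSpec", "rank_average_ensemble", "build_ensemble_grid"]


@dataclass(frozen=True)
class EnsembleSpec:
    name: str
    grouping: str  # per_category | per_algorithm | grand | custom
    members: tuple  # member model ids / (category, learner) keys


def rank_average_ensemble(predictions) -> pd.Series:
    """Average the within-roster ranks of one or more prediction vectors.

    All members must share one sample roster; with a single member the
    output is rank-equivalent to it (identical c-index).
    """
    preds = list(predictions)
    if not preds:
        raise ValueError("ensemble needs at least one member")
    index = preds[0].index
    for p in preds[1:]:
        if not p.index.equals(index):
            raise ValueError("ensemble members on different sample rosters")
    ranks = np.stack([rankdata(p.to_numpy(float), method="average") for p in preds])
    return pd.Series(ranks.mean(axis=0), index=index, name="ensemble_rank")


def build_ensemble_grid(predictions: dict) -> list:
    """All default ensembles from a complete (category, learner) prediction grid.

    Parameters
    ----------
    predictions : dict mapping (category, learner) -> prediction Series

    Returns
    -------
    list of (EnsembleSpec, Series); one per category, one per learner, one
    grand — ``n_categories + n_learners + 1`` in total.  A missing grid cell
    raises with the offending cells listed.
    """
    categories = sorted({c for c, _ in predictions})
    learners = sorted({l for _, l in predictions})
    missing = [(c, l) for c in categories for l in learners if (c, l) not in predictions]
    if missing:
        raise ValueError(f"incomplete prediction grid; missing cells: {missing}")
    out = []
    for c in categories:
        members = tuple((c, l) for l in learners)
        out.append((
            EnsembleSpec(name=f"ensemble_category:{c}", grouping="per_category", members=members),
            rank_average_ensemble([predictions[m] for m in members]),
        ))
    for l in learners:
        members = tuple((c, l) for c in categories)
        out.append((
            EnsembleSpec(name=f"ensemble_learner:{l}", grouping="per_algorithm", members=members),
            rank_average_ensemble([predictions[m] for m in members]),
        ))
    members = tuple((c, l) for c in categories for l in learners)
    out.append((
        EnsembleSpec(name="ensemble_grand", grouping="grand", members=members),
        rank_average_ensemble([predictions[m] for m in members]),
    ))
    return out
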