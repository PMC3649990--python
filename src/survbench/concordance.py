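"""Exact concordance index and bootstrap paired model comparison.

The concordance index (c-index) is computed exactly by enumerating *all*
unordered sample pairs rather than sampling them, so the statistic is
deterministic and platform-stable.  Conventions (Harrell-style):

* a pair is *comparable* iff the observed times differ and the sample with
  the smaller time experienced the event (otherwise its true ordering is
  unknown under right censoring);
* a comparable pair is *concordant* when the smaller-time sample also has
  the smaller predicted-survival score (predictions are "higher = longer
  predicted survival");
* tied predictions receive half credit.

Pairs with tied observed event times are excluded as non-comparable.
Arithmetic is kept in integer half-credit units until the final division.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConcordanceResult",
    "NoComparablePairsError",
    "concordance_index",
    "bootstrap_paired_comparison",
]


class NoComparablePairsError(ValueError):
    """All pairs are incomparable (e.g. every sample censored)."""


@dataclass(frozen=True)
class ConcordanceResult:
    """Exact c-index with its pair bookkeeping.

    ``n_concordant`` counts concordant pairs with prediction ties counted as
    0.5, so ``c_index == n_concordant / n_comparable_pairs``.
    """

    c_index: float
    n_comparable_pairs: int
    n_concordant: float


def _as_arrays(pred, outcome):
    if hasattr(outcome, "time"):
        time = np.asarray(outcome.time, dtype=float)
        event = np.asarray(outcome.event, dtype=int)
        if isinstance(pred, pd.Series) and hasattr(outcome, "samples"):
            pred = pred.loc[outcome.samples]
    else:
        time, event = (np.asarray(a) for a in outcome)
    pred = np.asarray(pred, dtype=float)
    if pred.shape != time.shape:
        raise ValueError("prediction and outcome have different lengths")
    if not np.all(np.isfinite(pred)):
        raise ValueError("predictions must be finite")
    return pred, time, event


def concordance_index(pred, outcome) -> ConcordanceResult:
    """Exact c-index of a predicted-survival vector against a censored outcome.

    Parameters
    ----------
    pred : array-like or Series
        Per-sample predicted survival score, higher = longer predicted
        survival.  If a Series and ``outcome`` carries a roster, it is
        aligned by sample id.
    outcome : SurvivalOutcome or (time, event) pair

    Returns
    -------
    ConcordanceResult

    Raises
    ------
    NoComparablePairsError
        If no pair is comparable; this is an explicit error, never 0.5.
    """
    pred, time, event = _as_arrays(pred, outcome)
    n = len(pred)
    if n < 2:
        raise ValueError("need at least 2 samples")
    # comparable[i, j]: time_i < time_j and event_i == 1
    earlier = time[:, None] < time[None, :]
    comparable = earlier & (event[:, None] == 1)
    # credit in half units: 2 = concordant, 1 = prediction tie, 0 = discordant
    less = pred[:, None] < pred[None, :]
    tied = pred[:, None] == pred[None, :]
    credit_half = int(2 * np.count_nonzero(comparable & less)) + int(
        np.count_nonzero(comparable & tied)
    )
    n_pairs = int(np.count_nonzero(comparable))
    if n_pairs == 0:
        raise NoComparablePairsError("no comparable pairs (all censored or all times tied)")
    return ConcordanceResult(
        c_index=credit_half / (2 * n_pairs),
        n_comparable_pairs=n_pairs,
        n_concordant=credit_half / 2,
    )


def bootstrap_paired_comparison(
    pred_a,
    pred_b,
    outcome,
    n_boot: int = 100,
    seed: int | None = None,
    max_redraws: int = 1000,
):
    """Paired Wilcoxon signed-rank comparison of two models over bootstrap resamples.

    Draws ``n_boot`` bootstrap resamples of the sample roster (with
    replacement), scores both prediction vectors on each resample with the
    exact c-index, and tests the paired per-replicate differences with a
    two-sided Wilcoxon signed-rank test.  Resamples with no comparable pairs
    are redrawn.

    Returns
    -------
    (p_value, pairs) : float, ndarray of shape (n_boot, 2)
        ``pairs[j] = (c_index_a, c_index_b)`` on resample j.
    """
    pred_a, time, event = _as_arrays(pred_a, outcome)
    pred_b, _, _ = _as_arrays(pred_b, outcome)
    rng = np.random.default_rng(seed)
    n = len(time)
    pairs = np.empty((n_boot, 2))
    redraws = 0
    j = 0
    while j < n_boot:
        idx = rng.integers(0, n, size=n)
        try:
            ca = concordance_index(pred_a[idx], (time[idx], event[idx]))
            cb = concordance_index(pred_b[idx], (time[idx], event[idx]))
        except NoComparablePairsError:
            redraws += 1
            if redraws > max_redraws:
                raise
            continue
        pairs[j] = (ca.c_index, cb.c_index)
        j += 1
    diffs = pairs[:, 0] - pairs[:, 1]
    if np.all(diffs == 0):
        return 1.0, pairs
    p = float(stats.wilcoxon(pairs[:, 0], pairs[:, 1], zero_method="wilcox").pvalue)
    return p, pairs
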