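"""Published-style gene-expression prognosis signatures.

Two recomputation procedures are provided as pluggable prediction
generators: a weighted-sum score over z-scored expression (the 21-gene
recurrence-score style) and a good-prognosis centroid-correlation score (the
70-gene style, where each patient is scored by the correlation of their
signature-gene profile with the mean profile of long survivors).  Either
signature's gene list can also be used as a feature set for the model grid.

The actual commercial gene lists and weights are licensed; synthetic
stand-ins ship with the cohort generator and real lists are user-supplied
files (TSV of gene/weight for weighted signatures, a newline-separated gene
list for centroid signatures).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, SurvivalOutcome
from .features import FeatureSet

logger = logging.getLogger(__name__)

__all__ = [
    "WeightedSignature",
    "CentroidSignature",
    "weighted_signature_score",
    "centroid_signature_score",
    "signature_as_feature_set",
]


@dataclass
class WeightedSignature:
    """Gene ids with signed risk weights (higher weighted sum = higher risk)."""

    name: str
    weights: dict  # gene -> weight

    def __post_init__(self):
        if not self.weights:
            raise ValueError("signature needs at least one gene")
        if not all(np.isfinite(list(self.weights.values()))):
            raise ValueError("weights must be finite")


@dataclass
class CentroidSignature:
    """Gene ids scored by correlation to a good-prognosis average profile."""

    name: str
    genes: list = field(default_factory=list)
    good_prognosis_horizon: float = 60.0  # months

    def __post_init__(self):
        if not self.genes:
            raise ValueError("signature needs at least one gene")
        if self.good_prognosis_horizon <= 0:
            raise ValueError("horizon must be positive")


def _zscore(expr: pd.DataFrame, ref_samples=None) -> pd.DataFrame:
    """Per-gene z-scores; statistics from ``ref_samples`` when given.

    Zero-variance genes are dropped (logged) since they carry no ranking
    information and would divide by zero.
    """
    ref = expr[ref_samples] if ref_samples is not None else expr
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=0)
    keep = sd > 0
    if (~keep).any():
        logger.info("dropping %d zero-variance genes from signature", int((~keep).sum()))
    return expr.loc[keep].sub(mu[keep], axis=0).div(sd[keep], axis=0)


def weighted_signature_score(expr: pd.DataFrame, sig: WeightedSignature,
                             train_samples=None) -> pd.Series:
    """Weighted sum of z-scored expression, returned on the survival scale.

    Genes are z-scored across samples (training statistics when a split is
    given); missing signature genes are dropped with a log message.  The
    weighted sum measures *risk*, so the returned prediction vector is its
    negation (higher = longer predicted survival).
    """
    present = [g for g in sig.weights if g in expr.index]
    if not present:
        raise ValueError("no signature genes present in the expression matrix")
    if len(present) < len(sig.weights):
        logger.info("signature %s: %d of %d genes absent, dropped", sig.name,
                    len(sig.weights) - len(present), len(sig.weights))
    z = _zscore(expr.loc[present], train_samples)
    w = pd.Series({g: sig.weights[g] for g in z.index})
    risk = z.mul(w, axis=0).sum(axis=0)
    return (-risk).rename(f"{sig.name}_score")


def centroid_signature_score(expr: pd.DataFrame, sig: CentroidSignature,
                             outcome: SurvivalOutcome, train_samples=None) -> pd.Series:
    """Correlation of each sample to the average good-prognosis profile.

    The reference profile is the mean standardized expression of the
    signature genes over samples observed to survive past the horizon
    (patients censored before the horizon are excluded from the reference,
    since their survival past it is unknown).  Higher score = better
    prognosis; no negation needed.
    """
    present = [g for g in sig.genes if g in expr.index]
    if len(present) < 3:
        raise ValueError("need at least 3 signature genes present")
    z = _zscore(expr.loc[present], train_samples)
    lived_past = outcome.time > sig.good_prognosis_horizon
    ref = outcome.samples[lived_past.to_numpy()]
    if len(ref) < 2:
        raise ValueError("fewer than 2 good-prognosis reference samples")
    profile = z[ref].mean(axis=1).to_numpy()
    mat = z.to_numpy(float)
    pc = profile - profile.mean()
    mc = mat - mat.mean(axis=0)
    denom = np.linalg.norm(mc, axis=0) * np.linalg.norm(pc)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.where(denom > 0, mc.T @ pc / denom, 0.0)
    return pd.Series(corr, index=z.columns, name=f"{sig.name}_score")


def signature_as_feature_set(sig, cohort: Cohort) -> FeatureSet:
    """Expose a signature's gene list as an expression feature set for the grid."""
    genes = list(sig.weights) if isinstance(sig, WeightedSignature) else list(sig.genes)
    present = [g for g in genes if g in cohort.expression.index]
    if not present:
        raise ValueError("signature genes do not intersect cohort genes")
    if len(present) < len(genes):
        logger.info("signature %s: %d genes absent from cohort, dropped",
                    sig.name, len(genes) - len(present))
    return FeatureSet(
        name=f"signature:{sig.name}",
        ids=[f"expr:{g}" for g in present],
        provenance={"strategy": "signature", "signature": sig.name,
                    "n_requested": len(genes)},
    )
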