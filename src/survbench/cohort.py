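"""Core in-memory containers for a prognosis cohort.

A cohort bundles the three data modalities used throughout the framework
(gene expression, segmented copy number, clinical covariates) together with
the censored survival outcome and a fixed train/validation split.  All
components are pandas objects sharing one sample roster; :meth:`Cohort.validate`
enforces that agreement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

SEGMENT_COLUMNS = ["sample", "chromosome", "start", "end", "logR"]

#: Full clinical covariate roster emitted by the synthetic generator.
CLINICAL_COLUMNS = [
    "ageDiagnosis",
    "tumorSizeCM",
    "lymphnodes",
    "grade",
    "ER",
    "PR",
    "HER2",
    "hormone",
    "radiation",
    "chemo",
    "histology",
    "tripleNegative",
    "ERPR",
]

HISTOLOGY_LEVELS = ["ILC", "IDC", "mixed", "medullary", "mucinous"]


class RosterMismatchError(ValueError):
    """Raised when cohort components disagree on the sample roster."""


@dataclass
class SurvivalOutcome:
    """Right-censored follow-up: time in months and a binary event flag.

    ``event == 1`` means death observed at ``time``; ``event == 0`` means the
    patient was censored at ``time`` (their survival time is only known to
    exceed it).
    """

    time: pd.Series
    event: pd.Series

    def __post_init__(self) -> None:
        self.time = pd.Series(self.time, dtype=float)
        self.event = pd.Series(self.event, dtype=int)
        if not self.time.index.equals(self.event.index):
            raise RosterMismatchError("time and event indexed by different samples")
        if not np.all(np.isfinite(self.time.values)) or (self.time.values <= 0).any():
            raise ValueError("follow-up times must be finite and positive")
        if not set(np.unique(self.event.values)) <= {0, 1}:
            raise ValueError("event indicator must be binary")

    @property
    def samples(self) -> pd.Index:
        return self.time.index

    def loc(self, samples) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time.loc[samples], self.event.loc[samples])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_months": self.time, "event": self.event})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SurvivalOutcome":
        return cls(df["time_months"], df["event"])

    def __len__(self) -> int:
        return len(self.time)

    def __eq__(self, other) -> bool:  # pragma: no cover - convenience
        return (
            isinstance(other, SurvivalOutcome)
            and self.time.equals(other.time)
            and self.event.equals(other.event)
        )


def validate_clinical(clinical: pd.DataFrame) -> None:
    """Check the derived-flag and level invariants of a clinical table."""
    missing = [c for c in CLINICAL_COLUMNS if c not in clinical.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    if not clinical["grade"].isin([1, 2, 3]).all():
        raise ValueError("grade must be ordinal in {1,2,3}")
    tn = (clinical["ER"] == 0) & (clinical["PR"] == 0) & (clinical["HER2"] == 0)
    if not (clinical["tripleNegative"].astype(bool) == tn).all():
        raise ValueError("tripleNegative flag inconsistent with ER/PR/HER2")
    erpr = (clinical["ER"] == 1) | (clinical["PR"] == 1)
    if not (clinical["ERPR"].astype(bool) == erpr).all():
        raise ValueError("ERPR flag inconsistent with ER/PR")


@dataclass
class Cohort:
    """Expression + copy number + clinical + outcome for one sample roster.

    Attributes
    ----------
    expression : DataFrame, genes x samples
        Log-intensity gene expression.
    segments : DataFrame
        SEG-style table with columns ``sample, chromosome, start, end, logR``;
        coordinates are 1-based inclusive base pairs.
    cn_genes : DataFrame, genes x samples
        Gene-level segmented copy-number log-ratios (NaN where a gene overlaps
        no segment for a sample).
    clinical : DataFrame, samples x covariates
    outcome : SurvivalOutcome
    split : Series mapping sample -> {"train", "validation"}
    genes : DataFrame
        Gene annotation with columns ``chromosome, start, end`` indexed by
        gene id (1-based inclusive coordinates).
    gene_lists : dict
        Named prior gene lists (synthetic stand-ins or user supplied).
    truth : dict or None
        Planted generator parameters; synthetic cohorts only.
    """

    expression: pd.DataFrame
    segments: pd.DataFrame
    cn_genes: pd.DataFrame
    clinical: pd.DataFrame
    outcome: SurvivalOutcome
    split: pd.Series
    genes: pd.DataFrame | None = None
    gene_lists: dict = field(default_factory=dict)
    truth: dict | None = None

    @property
    def samples(self) -> pd.Index:
        return self.outcome.samples

    @property
    def train_samples(self) -> pd.Index:
        return self.split.index[self.split == "train"]

    @property
    def validation_samples(self) -> pd.Index:
        return self.split.index[self.split == "validation"]

    def validate(self) -> None:
        roster = set(self.samples)
        for name, cols in [
            ("expression", self.expression.columns),
            ("cn_genes", self.cn_genes.columns),
            ("clinical", self.clinical.index),
            ("split", self.split.index),
        ]:
            if len(cols) and set(cols) != roster:
                raise RosterMismatchError(f"{name} roster differs from outcome roster")
        seg_samples = set(self.segments["sample"].unique())
        if seg_samples and not seg_samples <= roster:
            raise RosterMismatchError("segments contain samples absent from outcome")
        if not self.split.isin(["train", "validation"]).all():
            raise ValueError("split labels must be 'train' or 'validation'")
        if len(self.clinical):
            validate_clinical(self.clinical)

    def equals(self, other: "Cohort") -> bool:
        return (
            self.expression.equals(other.expression)
            and self.segments.reset_index(drop=True).equals(other.segments.reset_index(drop=True))
            and self.cn_genes.equals(other.cn_genes)
            and self.clinical.equals(other.clinical)
            and self.outcome == other.outcome
            and self.split.equals(other.split)
        )
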