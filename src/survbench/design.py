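"""Feature categories and design-matrix assembly for the controlled experiment.

The controlled experiment's 15 feature categories are: six molecular
pre-selection strategies (marginal association, top-varying, cancer-census
list, Higgins-style oncogene variance, clustering gene list, MASP), the same
six plus all clinical covariates, clinical covariates alone, clinical + GII,
and clinical + GII + MASP.

Selection is always fitted on the training split and frozen: transforming a
cohort never re-selects features, and validation samples cannot influence a
feature set.  A :class:`FittedCategory` can be re-applied to an independent
cohort sharing the feature namespace (for cross-cohort consistency scoring).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import Cohort, HISTOLOGY_LEVELS
from .features import (
    FeatureSet,
    GiiThresholds,
    genomic_instability_index,
    masp_select,
    select_from_prior_list,
    select_marginal_association,
    select_top_varying,
)

logger = logging.getLogger(__name__)

MOLECULAR_STRATEGIES = [
    "marginal_association",
    "top_varying",
    "cancer_census",
    "higgins",
    "metabric_clustering",
    "masp",
]

DEFAULT_CATEGORIES = (
    MOLECULAR_STRATEGIES
    + [s + "_clinical" for s in MOLECULAR_STRATEGIES]
    + ["clinical", "clinical_gii", "clinical_gii_masp"]
)

_BINARY_CLINICAL = [
    "lymphnodes", "ER", "PR", "HER2", "hormone", "radiation", "chemo",
    "tripleNegative", "ERPR",
]
_CONTINUOUS_CLINICAL = ["ageDiagnosis", "tumorSizeCM", "grade"]


@dataclass
class CategoryParams:
    """Tunable parameters shared by the category assemblers."""

    k_marginal: int = 1000
    k_variance: int = 1000
    k_higgins: int = 1000
    masp_chunk_size: int = 50
    masp_n_repeats: int = 100
    masp_k: int = 50
    gii_thresholds: GiiThresholds = field(default_factory=GiiThresholds)
    clinical_subset: list | None = None  # None = full roster
    gene_lists: dict | None = None  # override cohort.gene_lists
    seed: int = 0


def parse_category(name: str):
    """Split a category name into (molecular strategy | None, clinical, gii)."""
    if name == "clinical":
        return None, True, False
    if name == "clinical_gii":
        return None, True, True
    if name == "clinical_gii_masp":
        return "masp", True, True
    if name in MOLECULAR_STRATEGIES:
        return name, False, False
    if name.endswith("_clinical") and name[: -len("_clinical")] in MOLECULAR_STRATEGIES:
        return name[: -len("_clinical")], True, False
    raise ValueError(f"unknown feature category: {name!r}")


def encode_clinical(clinical: pd.DataFrame, subset: list | None = None) -> pd.DataFrame:
    """One-hot/ordinal encoding of the clinical roster with ``clin:`` ids.

    Histology is dummy-coded against the ILC baseline.  ``subset`` names
    roster covariates (pre-encoding) to keep; default all.
    """
    cols = subset if subset is not None else list(clinical.columns)
    out = {}
    for c in cols:
        if c in _CONTINUOUS_CLINICAL:
            out[f"clin:{c}"] = clinical[c].astype(float)
        elif c in _BINARY_CLINICAL:
            out[f"clin:{c}"] = clinical[c].astype(float)
        elif c == "histology":
            for level in HISTOLOGY_LEVELS[1:]:
                out[f"clin:hist_{level}"] = (clinical[c] == level).astype(float)
        else:
            raise ValueError(f"unknown clinical covariate: {c}")
    return pd.DataFrame(out, index=clinical.index)


@dataclass
class FittedCategory:
    """A frozen feature category: selected ids plus training statistics."""

    category: str
    feature_set: FeatureSet
    columns: list
    center: pd.Series  # imputation value and centering per scaled column
    scale: pd.Series
    clinical_subset: list | None
    gii_thresholds: GiiThresholds | None

    def transform(self, cohort: Cohort, samples=None) -> pd.DataFrame:
        """Build the design matrix for ``samples`` (default: full roster)."""
        samples = pd.Index(samples) if samples is not None else cohort.samples
        blocks = []
        mol_ids = [f for f in self.feature_set.ids if f.startswith(("expr:", "cna:"))]
        if mol_ids:
            rows = []
            for fid in mol_ids:
                mod, _, gene = fid.partition(":")
                source = cohort.expression if mod == "expr" else cohort.cn_genes
                if gene not in source.index:
                    raise KeyError(f"feature {fid} absent from cohort (namespace mismatch)")
                rows.append(source.loc[gene, samples])
            blocks.append(pd.DataFrame(dict(zip(mol_ids, rows)), index=samples))
        if self.clinical_subset is not None or any(
            f.startswith("clin:") for f in self.feature_set.ids
        ):
            enc = encode_clinical(cohort.clinical.loc[samples], self.clinical_subset)
            blocks.append(enc)
        if self.gii_thresholds is not None:
            gii = genomic_instability_index(cohort.cn_genes[samples], self.gii_thresholds)
            blocks.append(gii.rename("agg:gii").to_frame())
        X = pd.concat(blocks, axis=1)[self.columns]
        # impute with training means, then center/scale continuous columns
        X = X.fillna(self.center)
        scaled = list(self.scale.index)
        if scaled:
            X[scaled] = (X[scaled] - self.center.loc[scaled]) / self.scale.loc[scaled]
        return X


def fit_category(cohort: Cohort, category: str, params: CategoryParams | None = None) -> FittedCategory:
    """Fit a feature category on the cohort's training split and freeze it."""
    params = params or CategoryParams()
    strategy, use_clinical, use_gii = parse_category(category)
    train = cohort.train_samples
    lists = params.gene_lists if params.gene_lists is not None else cohort.gene_lists
    matrices = {"expr": cohort.expression, "cna": cohort.cn_genes}

    ids = []
    provenance = {"category": category}
    if strategy is not None:
        if cohort.expression.empty and cohort.cn_genes.empty:
            raise ValueError(f"category {category!r} needs molecular data, none present")
        if strategy == "marginal_association":
            fs = select_marginal_association(matrices, cohort.outcome, train, k=params.k_marginal)
        elif strategy == "top_varying":
            fs = select_top_varying(matrices, train, k=params.k_variance)
        elif strategy == "cancer_census":
            fs = select_from_prior_list(matrices, lists["census_like"], k=None,
                                        samples=train, name="cancer_census")
        elif strategy == "higgins":
            fs = select_from_prior_list(matrices, lists["oncogene_tf"], k=params.k_higgins,
                                        samples=train, name="higgins")
        elif strategy == "metabric_clustering":
            fs = select_from_prior_list(matrices, lists["clustering_like"], k=None,
                                        samples=train, name="metabric_clustering")
        elif strategy == "masp":
            fs, _ = masp_select(
                cohort.expression, cohort.outcome, lists["oncogene_tf"], train,
                chunk_size=params.masp_chunk_size, n_repeats=params.masp_n_repeats,
                k=params.masp_k, seed=params.seed,
            )
        else:  # pragma: no cover - guarded by parse_category
            raise ValueError(strategy)
        ids.extend(fs.ids)
        provenance["molecular"] = fs.provenance
    clinical_subset = None
    if use_clinical:
        clinical_subset = params.clinical_subset or list(cohort.clinical.columns)
        enc_cols = list(encode_clinical(cohort.clinical.iloc[:2], clinical_subset).columns)
        ids.extend(enc_cols)
    if use_gii:
        ids.append("agg:gii")
    feature_set = FeatureSet(name=category, ids=ids, provenance=provenance)

    fitted = FittedCategory(
        category=category,
        feature_set=feature_set,
        columns=list(ids),
        center=pd.Series(dtype=float),
        scale=pd.Series(dtype=float),
        clinical_subset=clinical_subset,
        gii_thresholds=params.gii_thresholds if use_gii else None,
    )
    _fit_statistics(fitted, cohort)
    return fitted


def _fit_statistics(fitted: FittedCategory, cohort: Cohort) -> None:
    """Freeze imputation/centering/scaling statistics from the training split."""
    X_train = fitted.transform_raw(cohort, cohort.train_samples)
    binary = [c for c in X_train.columns
              if c.startswith("clin:") and c.split(":", 1)[1] not in _CONTINUOUS_CLINICAL]
    scaled_cols = [c for c in X_train.columns if c not in binary]
    center = X_train.mean()
    center[binary] = 0.0
    scale = X_train[scaled_cols].std(ddof=0).replace(0.0, 1.0).fillna(1.0)
    fitted.center = center.fillna(0.0)
    fitted.scale = scale


def freeze_feature_ids(cohort: Cohort, name: str, ids, clinical_subset: list | None = None,
                       gii_thresholds: GiiThresholds | None = None,
                       provenance: dict | None = None) -> FittedCategory:
    """Freeze an explicit list of feature ids as a custom category.

    Used for ad-hoc designs such as the random-feature null models
    (clinical + a random molecular draw).  ``ids`` should include the
    encoded clinical column ids when ``clinical_subset`` is given and
    ``agg:gii`` when ``gii_thresholds`` is given.
    """
    fitted = FittedCategory(
        category=name,
        feature_set=FeatureSet(name=name, ids=list(ids), provenance=provenance or {}),
        columns=list(ids),
        center=pd.Series(dtype=float),
        scale=pd.Series(dtype=float),
        clinical_subset=clinical_subset,
        gii_thresholds=gii_thresholds,
    )
    _fit_statistics(fitted, cohort)
    return fitted


def _transform_raw(self: FittedCategory, cohort: Cohort, samples=None) -> pd.DataFrame:
    """Design matrix before imputation/scaling (used to fit the statistics)."""
    saved_center, saved_scale = self.center, self.scale
    self.center = pd.Series(np.nan, index=self.columns)
    self.scale = pd.Series(dtype=float)
    try:
        X = self.transform(cohort, samples)
    finally:
        self.center, self.scale = saved_center, saved_scale
    return X


FittedCategory.transform_raw = _transform_raw


def assemble_feature_matrix(cohort: Cohort, category: str,
                            params: CategoryParams | None = None) -> pd.DataFrame:
    """Samples x features design matrix for one category (selection fit on train).

    Convenience wrapper over :func:`fit_category` returning the matrix for
    the full roster; use :func:`fit_category` directly to keep the frozen
    category for re-use on other cohorts.
    """
    return fit_category(cohort, category, params).transform(cohort)
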