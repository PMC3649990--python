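"""Feature engineering and selection for prognosis benchmarking.

This module houses the copy-number summarizations, the genomic instability
index (GII), univariate Cox screening, the named feature-selection
strategies of the controlled experiment, and MASP (Marginal Association with
Subsampling and Prior knowledge).

Feature ids carry a modality prefix: ``expr:<gene>``, ``cna:<gene>``,
``clin:<covariate>``, ``agg:<name>``.  All coordinates are 1-based inclusive
and overlap means any shared base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cox import batch_univariate_cox, univariate_cox_score  # noqa: F401  (re-export)

logger = logging.getLogger(__name__)

__all__ = [
    "GiiThresholds",
    "FeatureSet",
    "MaspScoreTable",
    "segments_to_gene_matrix",
    "probes_to_genes_eigengene",
    "genomic_instability_index",
    "univariate_cox_score",
    "select_marginal_association",
    "select_top_varying",
    "select_from_prior_list",
    "masp_select",
]


@dataclass(frozen=True)
class GiiThresholds:
    """Amplification/deletion cutoffs on segmented log2 ratios.

    Defaults of +/-0.3 are conventional for single-copy gains/losses on
    segmented array data.
    """

    tau_amp: float = 0.3
    tau_del: float = -0.3

    def __post_init__(self):
        if not (self.tau_del < 0 < self.tau_amp):
            raise ValueError("need tau_del < 0 < tau_amp")


@dataclass
class FeatureSet:
    """A named selection of cohort features with its provenance."""

    name: str
    ids: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("feature ids must be unique")

    def genes(self) -> list:
        """Gene ids referenced by molecular features (order-preserving, unique)."""
        out, seen = [], set()
        for fid in self.ids:
            mod, _, name = fid.partition(":")
            if mod in ("expr", "cna") and name not in seen:
                seen.add(name)
                out.append(name)
        return out

    def __len__(self):
        return len(self.ids)


@dataclass
class MaspScoreTable:
    """Per-gene p-values across subsampling repeats and the aggregate score.

    ``score[i] = sum_j -log10(p[i, j])`` over repeats j.
    """

    p_values: pd.DataFrame  # genes x repeats
    score: pd.Series  # aggregate per gene


# ---------------------------------------------------------------------------
# copy-number summarization


def segments_to_gene_matrix(segments: pd.DataFrame, genes: pd.DataFrame) -> pd.DataFrame:
    """Summarize segmented copy number to the gene level.

    Per gene and sample, the value is the *unweighted* mean of the segmented
    log-ratios of all segments overlapping the gene interval (any overlap
    counts); a gene overlapping no segment gets NaN.

    Parameters
    ----------
    segments : DataFrame with columns sample, chromosome, start, end, logR
        1-based inclusive coordinates; per sample/chromosome non-overlapping.
    genes : DataFrame indexed by gene id with columns chromosome, start, end.
    """
    if (segments["start"] > segments["end"]).any():
        raise ValueError("malformed segment coordinates (start > end)")
    if (genes["start"] > genes["end"]).any():
        raise ValueError("malformed gene coordinates (start > end)")
    samples = pd.Index(pd.unique(segments["sample"]))
    out = pd.DataFrame(np.nan, index=genes.index, columns=samples)
    gene_by_chrom = {str(c): sub for c, sub in genes.groupby("chromosome")}
    for (sample, chrom), seg in segments.groupby(["sample", "chromosome"], sort=False):
        gsub = gene_by_chrom.get(str(chrom))
        if gsub is None:
            continue
        seg = seg.sort_values("start")
        starts = seg["start"].to_numpy(float)
        ends = seg["end"].to_numpy(float)
        logr = seg["logR"].to_numpy(float)
        csum = np.concatenate([[0.0], np.cumsum(logr)])
        g_start = gsub["start"].to_numpy(float)
        g_end = gsub["end"].to_numpy(float)
        # non-overlapping sorted segments: ends are sorted too
        i0 = np.searchsorted(ends, g_start, side="left")
        i1 = np.searchsorted(starts, g_end, side="right") - 1
        hit = i0 <= i1
        vals = np.full(len(gsub), np.nan)
        vals[hit] = (csum[i1[hit] + 1] - csum[i0[hit]]) / (i1[hit] - i0[hit] + 1)
        out.loc[gsub.index, sample] = vals
    return out


def probes_to_genes_eigengene(probe_matrix: pd.DataFrame, probe_to_gene) -> pd.DataFrame:
    """Summarize probe-level measurements to genes, weighting by the first eigengene.

    One probe: passthrough.  Two probes: unweighted mean.  More than two:
    singular value decomposition of the (row-centered) probe-by-sample block;
    each probe's weight is the fraction of its variance explained by the
    first eigengene, and the gene value is the weighted mean of the raw
    probe rows.  A zero-variance block falls back to the unweighted mean.
    """
    mapping = pd.Series(probe_to_gene)
    mapping = mapping.loc[mapping.index.intersection(probe_matrix.index)]
    rows = {}
    for gene, probes in mapping.groupby(mapping).groups.items():
        block = probe_matrix.loc[list(probes)].to_numpy(float)
        if block.shape[0] == 1:
            rows[gene] = block[0]
        elif block.shape[0] == 2:
            rows[gene] = block.mean(axis=0)
        else:
            centered = block - block.mean(axis=1, keepdims=True)
            total = np.sum(centered**2, axis=1)
            if np.all(total == 0):
                logger.warning("constant probe block for gene %s; unweighted mean", gene)
                rows[gene] = block.mean(axis=0)
                continue
            u, s, vt = np.linalg.svd(centered, full_matrices=False)
            per_probe_first = (s[0] * u[:, 0]) ** 2
            with np.errstate(invalid="ignore", divide="ignore"):
                weights = np.where(total > 0, per_probe_first / total, 0.0)
            if weights.sum() == 0:
                rows[gene] = block.mean(axis=0)
            else:
                rows[gene] = weights @ block / weights.sum()
    return pd.DataFrame(rows, index=probe_matrix.columns).T


def genomic_instability_index(cn: pd.DataFrame, thr: GiiThresholds | None = None) -> pd.Series:
    """Per-sample fraction of loci called amplified or deleted.

    ``GII = #(logR > tau_amp or logR < tau_del) / #non-missing loci``,
    computed over the rows of ``cn`` (loci or gene-level values x samples).
    Missing values are excluded from numerator and denominator; an
    all-missing sample is an error.
    """
    thr = thr or GiiThresholds()
    vals = cn.to_numpy(float)
    present = np.isfinite(vals)
    n_present = present.sum(axis=0)
    if (n_present == 0).any():
        bad = cn.columns[n_present == 0].tolist()
        raise ValueError(f"samples with no non-missing copy-number loci: {bad}")
    aberrant = present & ((vals > thr.tau_amp) | (vals < thr.tau_del))
    return pd.Series(aberrant.sum(axis=0) / n_present, index=cn.columns, name="gii")


# ---------------------------------------------------------------------------
# selection strategies


def _molecular_table(matrices: dict, samples) -> pd.DataFrame:
    """Stack modality matrices into one features x samples table with prefixed ids."""
    parts = []
    for modality in sorted(matrices):
        m = matrices[modality]
        if m is None or m.empty:
            continue
        sub = m[samples] if samples is not None else m
        sub = sub.copy()
        sub.index = [f"{modality}:{g}" for g in sub.index]
        parts.append(sub)
    if not parts:
        raise ValueError("no molecular features available")
    return pd.concat(parts, axis=0)


def select_marginal_association(matrices: dict, outcome, samples, k: int = 1000) -> FeatureSet:
    """Top-k molecular features by univariate Cox Wald p-value (ascending).

    Candidates are all expression and copy-number features; selection is fit
    on the given (training) samples only.  Ties in p-value break by feature
    id.  Features with missing values or zero variance score p = 1.
    """
    table = _molecular_table(matrices, samples)
    if len(table) < k:
        raise ValueError(f"only {len(table)} scorable features < k={k}")
    out = outcome.loc(samples) if hasattr(outcome, "loc") else outcome
    res = batch_univariate_cox(table.to_numpy(float).T, out.time, out.event)
    ids = np.asarray(table.index)
    order = np.lexsort((ids, res["p_value"]))
    chosen = ids[order][:k].tolist()
    return FeatureSet(
        name="marginal_association",
        ids=chosen,
        provenance={"strategy": "marginal_association", "k": k},
    )


def select_top_varying(matrices: dict, samples, k: int = 1000) -> FeatureSet:
    """Top-k molecular features by variance on the training samples."""
    table = _molecular_table(matrices, samples)
    if len(table) < k:
        raise ValueError(f"only {len(table)} features < k={k}")
    var = table.to_numpy(float).var(axis=1, ddof=1)
    var = np.where(np.isfinite(var), var, -np.inf)
    ids = np.asarray(table.index)
    order = np.lexsort((ids, -var))
    return FeatureSet(
        name="top_varying",
        ids=ids[order][:k].tolist(),
        provenance={"strategy": "top_varying", "k": k},
    )


def select_from_prior_list(matrices: dict, gene_list, k: int | None = None,
                           samples=None, name: str = "prior_list") -> FeatureSet:
    """Restrict molecular features to a prior gene list.

    ``k=None`` (census-style) returns every feature whose gene is in the
    list; with ``k`` (Higgins-style) the top-k by training-sample variance
    are kept, clamped (with a log message) when the intersection is smaller.
    """
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("empty prior gene list")
    table = _molecular_table(matrices, samples)
    genes = np.array([fid.partition(":")[2] for fid in table.index])
    mask = np.isin(genes, gene_list)
    if not mask.any():
        raise ValueError("prior list has no overlap with cohort features")
    sub = table[mask]
    if k is None:
        chosen = sorted(sub.index)
    else:
        if k > len(sub):
            logger.info("prior-list k=%d clamped to intersection size %d", k, len(sub))
            k = len(sub)
        var = sub.to_numpy(float).var(axis=1, ddof=1)
        var = np.where(np.isfinite(var), var, -np.inf)
        ids = np.asarray(sub.index)
        order = np.lexsort((ids, -var))
        chosen = ids[order][:k].tolist()
    return FeatureSet(name=name, ids=chosen,
                      provenance={"strategy": "prior_list", "k": k, "list_size": len(gene_list)})


def masp_select(expression: pd.DataFrame, outcome, prior_list, samples,
                chunk_size: int = 50, n_repeats: int = 100, k: int = 50,
                seed: int | None = None, max_redraws: int = 1000):
    """Marginal Association with Subsampling and Prior knowledge.

    For each of ``n_repeats`` repeats, draw ``chunk_size`` training samples
    without replacement (fresh draw per repeat) and score every gene's
    expression for association with survival by univariate Cox regression.
    Aggregate each gene's evidence as ``S_i = sum_j -log10 p_ij``, sort genes
    by ``S_i`` descending, and walk the sorted list keeping genes that are in
    the prior list until ``k`` are kept.

    Chunks with fewer than 2 events are redrawn (logged); genes unscorable in
    a chunk contribute p = 1.

    Returns
    -------
    (FeatureSet, MaspScoreTable)
    """
    samples = pd.Index(samples)
    if len(samples) < chunk_size:
        raise ValueError("training samples fewer than chunk_size")
    prior = set(prior_list)
    inter = [g for g in expression.index if g in prior]
    if len(inter) < k:
        raise ValueError(f"prior list intersects only {len(inter)} genes < k={k}")
    rng = np.random.default_rng(seed)
    out = outcome.loc(samples) if hasattr(outcome, "loc") else outcome
    time = np.asarray(out.time, float)
    event = np.asarray(out.event, int)
    expr = expression[samples].to_numpy(float)
    n = len(samples)
    pvals = np.ones((expression.shape[0], n_repeats))
    redraws = 0
    j = 0
    while j < n_repeats:
        idx = rng.choice(n, size=chunk_size, replace=False)
        if event[idx].sum() < 2:
            redraws += 1
            logger.info("MASP chunk %d redrawn: fewer than 2 events", j)
            if redraws > max_redraws:
                raise RuntimeError("could not draw a MASP chunk with >= 2 events")
            continue
        res = batch_univariate_cox(expr[:, idx].T, time[idx], event[idx])
        pvals[:, j] = res["p_value"]
        j += 1
    ptab = pd.DataFrame(pvals, index=expression.index,
                        columns=[f"repeat_{j}" for j in range(n_repeats)])
    score = pd.Series(-np.log10(pvals).sum(axis=1), index=expression.index, name="masp_score")
    ids = np.asarray(score.index)
    order = np.lexsort((ids, -score.to_numpy()))
    kept = []
    for g in ids[order]:
        if g in prior:
            kept.append(f"expr:{g}")
            if len(kept) == k:
                break
    fs = FeatureSet(
        name="masp",
        ids=kept,
        provenance={"strategy": "masp", "chunk_size": chunk_size,
                    "n_repeats": n_repeats, "k": k, "seed": seed},
    )
    return fs, MaspScoreTable(p_values=ptab, score=score)
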