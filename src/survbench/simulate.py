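"""Synthetic METABRIC-like cohort generator.

Emulates the statistical structure of a breast-cancer prognosis cohort with
planted, recoverable signal so that every downstream stage (feature
engineering, model grid, controls) is testable without access-controlled
patient data:

* a latent intrinsic subtype (luminal / basal / HER2) drives the ER/PR/HER2
  clinical markers and subtype-specific expression centroids;
* piecewise-constant copy-number segments whose aberration burden (GII)
  increases with a per-sample genomic-instability latent tied to subtype
  (strongest for HER2-positive tumors) and grade;
* clinical covariates follow the standard 16-covariate roster (age, tumor
  size, nodes, grade, receptor status, treatments, histology plus derived
  triple-negative and ER-or-PR flags);
* survival is proportional-hazards Weibull (default shape 1 = exponential)
  over the configured clinical, GII, and planted gene-module effects, with
  independent exponential censoring capped by an administrative follow-up
  horizon; the censoring rate is solved numerically to hit its target;
* a fixed train/validation split in the 500/480 style.

All randomness flows from a single seed via ``numpy.random.SeedSequence``
child streams (one per generated component), so cohorts are bit-identical
across runs with the same config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import optimize

from .cohort import Cohort, SurvivalOutcome, HISTOLOGY_LEVELS
from .features import GiiThresholds, segments_to_gene_matrix

__all__ = ["GeneratorConfig", "generate_cohort", "generate_prior_gene_lists"]

SUBTYPES = ["luminal", "basal", "her2"]

# marker positivity by subtype, P(positive)
_ER_BY_SUBTYPE = {"luminal": 0.92, "basal": 0.10, "her2": 0.25}
_HER2_BY_SUBTYPE = {"luminal": 0.08, "basal": 0.10, "her2": 0.95}
_GRADE_BY_SUBTYPE = {
    "luminal": [0.25, 0.50, 0.25],
    "basal": [0.05, 0.25, 0.70],
    "her2": [0.05, 0.35, 0.60],
}
_HISTOLOGY_PROBS = [0.12, 0.70, 0.10, 0.03, 0.05]  # ILC, IDC, mixed, medullary, mucinous


def _default_beta_clinical() -> dict:
    # log-hazard effects on standardized/indicator scale; directions follow
    # the usual clinical epidemiology of breast-cancer overall survival
    return {
        "ageDiagnosis": 0.45,
        "tumorSizeCM": 0.25,
        "lymphnodes": 0.40,
        "grade": 0.20,
        "PR": -0.25,
        "hormone": -0.30,
        "radiation": -0.15,
        "HER2": 0.20,
        "chemo": 0.10,
        "ER": -0.10,
    }


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic cohort generator (defaults = study conditions).

    ``n_samples`` and ``train_fraction`` default to a 980-patient cohort split
    500/480.  ``beta_*`` are log-hazard coefficients; ``beta_gii`` acts on the
    standardized realized genomic-instability fraction and ``beta_genes`` on
    the standardized mean expression of the planted prognostic gene module.
    Times are in months; ``admin_horizon`` is the administrative follow-up cap.
    """

    n_samples: int = 980
    n_genes: int = 2000
    n_chromosomes: int = 5
    n_cn_loci: int = 40  # per chromosome
    subtype_proportions: dict = field(
        default_factory=lambda: {"luminal": 0.55, "basal": 0.25, "her2": 0.20}
    )
    beta_clinical: dict = field(default_factory=_default_beta_clinical)
    beta_gii: float = 0.5
    beta_genes: float = 0.8
    module_size: int = 20
    er_amplitude: float = 1.2
    n_er_program: int = 30
    n_subtype_genes: int = 150
    weibull_shape: float = 1.0
    baseline_scale: float = 150.0
    censoring_rate: float = 0.55
    admin_horizon: float = 180.0
    train_fraction: float = 500 / 980
    seed: int = 0

    def validate(self) -> None:
        props = self.subtype_proportions
        if set(props) != set(SUBTYPES) or abs(sum(props.values()) - 1.0) > 1e-8:
            raise ValueError("subtype_proportions must be a simplex over luminal/basal/her2")
        if not (0.0 < self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in (0, 1)")
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must be in (0, 1)")
        for name in ("n_samples", "n_genes", "n_chromosomes", "n_cn_loci", "module_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        return cls(**d)


def _child_rngs(seed: int, names):
    children = np.random.SeedSequence(seed).spawn(len(names))
    return {name: np.random.default_rng(ss) for name, ss in zip(names, children)}


LOCUS_BP = 1_000_000  # width of one copy-number locus in base pairs


def _gene_annotation(config: GeneratorConfig) -> pd.DataFrame:
    """Place genes uniformly across the locus grid (10 kb intervals)."""
    n = config.n_genes
    gene_ids = [f"g{i:05d}" for i in range(n)]
    total_loci = config.n_chromosomes * config.n_cn_loci
    locus_of_gene = (np.arange(n) * total_loci) // n
    chrom = locus_of_gene // config.n_cn_loci + 1
    locus_in_chrom = locus_of_gene % config.n_cn_loci
    start = locus_in_chrom * LOCUS_BP + 100_000 + 1
    end = start + 10_000 - 1
    return pd.DataFrame(
        {"chromosome": chrom.astype(str), "start": start, "end": end}, index=gene_ids
    )


def _draw_segments(config, rng, p_aberrant, samples):
    """Alternating normal/aberrant runs over the per-chromosome locus grid."""
    mean_run = 8  # mean run length in loci
    rows = []
    locus_logr = np.zeros((config.n_chromosomes * config.n_cn_loci, len(samples)))
    for s_idx, sample in enumerate(samples):
        p_ab = p_aberrant[s_idx]
        for chrom in range(1, config.n_chromosomes + 1):
            pos = 0
            base = (chrom - 1) * config.n_cn_loci
            while pos < config.n_cn_loci:
                run = min(1 + rng.geometric(1.0 / mean_run), config.n_cn_loci - pos)
                if rng.random() < p_ab:
                    sign = 1.0 if rng.random() < 0.5 else -1.0
                    logr = rng.normal(sign * 0.6, 0.2)
                else:
                    logr = rng.normal(0.0, 0.05)
                rows.append(
                    (
                        sample,
                        str(chrom),
                        pos * LOCUS_BP + 1,
                        (pos + run) * LOCUS_BP,
                        round(float(logr), 4),
                    )
                )
                locus_logr[base + pos : base + pos + run, s_idx] = logr
                pos += run
    segments = pd.DataFrame(rows, columns=["sample", "chromosome", "start", "end", "logR"])
    return segments, locus_logr


def _solve_censoring_rate(t_event, u_cens, horizon, target):
    """Find the exponential censoring rate hitting the target censored fraction.

    Censoring time C = min(-log(u)/rate, horizon); a sample is censored when
    C < T.  The censored fraction is monotone increasing in rate, so the
    rate solves by bisection on the fixed uniform draws.  If the target is
    below the administrative floor (fraction with T > horizon), the smallest
    feasible rate is used.
    """

    def frac_censored(rate):
        c = np.minimum(-np.log(u_cens) / max(rate, 1e-12), horizon)
        return np.mean(c < t_event)

    floor = frac_censored(0.0)
    if target <= floor:
        return 1e-12
    lo, hi = 1e-8, 1.0
    while frac_censored(hi) < target and hi < 1e4:
        hi *= 4
    return optimize.brentq(lambda r: frac_censored(r) - target, lo, hi, xtol=1e-10)


def generate_cohort(config: GeneratorConfig) -> Cohort:
    """Generate a synthetic cohort with planted prognostic structure.

    Deterministic given ``config`` (including its seed).  The returned
    cohort's ``truth`` dict records every planted quantity: subtype, the
    instability latent, realized GII, the linear predictor, module and ER
    program gene ids, and the coefficients used.
    """
    config.validate()
    rngs = _child_rngs(
        config.seed,
        ["subtype", "clinical", "segments", "expression", "survival", "split", "lists"],
    )
    n = config.n_samples
    samples = pd.Index([f"s{i:04d}" for i in range(n)], name="sample")

    # --- latent subtype and clinical covariates -----------------------------
    rng = rngs["subtype"]
    probs = [config.subtype_proportions[s] for s in SUBTYPES]
    subtype = np.array(SUBTYPES)[rng.choice(len(SUBTYPES), size=n, p=probs)]

    rng = rngs["clinical"]
    er = (rng.random(n) < np.vectorize(_ER_BY_SUBTYPE.get)(subtype)).astype(int)
    pr = (rng.random(n) < np.where(er == 1, 0.80, 0.15)).astype(int)
    her2 = (rng.random(n) < np.vectorize(_HER2_BY_SUBTYPE.get)(subtype)).astype(int)
    grade = np.array(
        [rng.choice([1, 2, 3], p=_GRADE_BY_SUBTYPE[s]) for s in subtype], dtype=int
    )
    age = np.clip(rng.normal(61, 12, size=n), 25, 95).round(1)
    size = np.clip(np.exp(rng.normal(0.8, 0.45, size=n)), 0.3, 10.0).round(2)
    nodes = (rng.random(n) < 1 / (1 + np.exp(-(-0.5 + 0.3 * (size - 2.0))))).astype(int)
    hormone = (rng.random(n) < np.where(er == 1, 0.8, 0.1)).astype(int)
    chemo_lin = -1.0 + 0.8 * (grade - 2) + 0.8 * nodes - 0.03 * (age - 61)
    chemo = (rng.random(n) < 1 / (1 + np.exp(-chemo_lin))).astype(int)
    radiation = (rng.random(n) < 0.6).astype(int)
    histology = np.array(HISTOLOGY_LEVELS)[
        rng.choice(len(HISTOLOGY_LEVELS), size=n, p=_HISTOLOGY_PROBS)
    ]
    clinical = pd.DataFrame(
        {
            "ageDiagnosis": age,
            "tumorSizeCM": size,
            "lymphnodes": nodes,
            "grade": grade,
            "ER": er,
            "PR": pr,
            "HER2": her2,
            "hormone": hormone,
            "radiation": radiation,
            "chemo": chemo,
            "histology": histology,
            "tripleNegative": ((er == 0) & (pr == 0) & (her2 == 0)).astype(int),
            "ERPR": ((er == 1) | (pr == 1)).astype(int),
        },
        index=samples,
    )

    # --- copy number: instability latent -> segments -> gene level ----------
    rng = rngs["segments"]
    z_instab = (
        0.9 * her2
        + 0.35 * (grade - 2)
        + 0.3 * (subtype == "basal").astype(float)
        + rng.normal(0, 0.5, size=n)
    )
    p_aberrant = 0.03 + 0.45 / (1 + np.exp(-1.2 * (z_instab - 0.4)))
    segments, locus_logr = _draw_segments(config, rng, p_aberrant, samples)
    genes = _gene_annotation(config)
    cn_genes = segments_to_gene_matrix(segments, genes)[samples]
    thr = GiiThresholds()
    aberrant = (locus_logr > thr.tau_amp) | (locus_logr < thr.tau_del)
    gii_true = aberrant.mean(axis=0)

    # --- expression ---------------------------------------------------------
    rng = rngs["expression"]
    gene_ids = genes.index
    expr = rng.normal(0.0, 1.0, size=(config.n_genes, n))
    # subtype centroids on the first block of genes
    n_sub = min(config.n_subtype_genes, config.n_genes)
    centroids = rng.normal(0.0, 0.8, size=(n_sub, len(SUBTYPES)))
    sub_idx = np.array([SUBTYPES.index(s) for s in subtype])
    expr[:n_sub] += centroids[:, sub_idx]
    # ER-driven program on the next block; gene er0 is the designated
    # "ER expression measurement" (strongly tied to ER status)
    er_start = n_sub
    n_er = min(config.n_er_program, config.n_genes - er_start)
    expr[er_start : er_start + n_er] += config.er_amplitude * er[None, :]
    expr[er_start] += 0.8 * er[None, :].ravel()  # designated ER gene, extra separation
    er_program = list(gene_ids[er_start : er_start + n_er])
    er_gene = gene_ids[er_start]
    # planted prognostic module driven by a per-sample latent factor
    mod_start = er_start + n_er
    module = list(gene_ids[mod_start : mod_start + config.module_size])
    u_prog = rng.normal(0.0, 1.0, size=n)
    expr[mod_start : mod_start + config.module_size] = (
        0.9 * u_prog[None, :]
        + rng.normal(0.0, 0.6, size=(config.module_size, n))
    )
    expression = pd.DataFrame(np.round(expr, 4), index=gene_ids, columns=samples)
    module_score = expression.loc[module].mean(axis=0).to_numpy()

    # --- survival -----------------------------------------------------------
    rng = rngs["survival"]

    def std(x):
        s = x.std(ddof=0)
        return (x - x.mean()) / s if s > 0 else x * 0.0

    lp = np.zeros(n)
    covs = {
        "ageDiagnosis": std(age),
        "tumorSizeCM": std(size),
        "lymphnodes": nodes,
        "grade": grade - 2,
        "ER": er,
        "PR": pr,
        "HER2": her2,
        "hormone": hormone,
        "radiation": radiation,
        "chemo": chemo,
    }
    for name, beta in config.beta_clinical.items():
        if name not in covs:
            raise ValueError(f"unknown clinical covariate in beta_clinical: {name}")
        lp += beta * np.asarray(covs[name], dtype=float)
    lp += config.beta_gii * std(gii_true)
    lp += config.beta_genes * std(module_score)
    lp -= lp.mean()
    t_event = config.baseline_scale * (
        rng.exponential(1.0, size=n) / np.exp(lp)
    ) ** (1.0 / config.weibull_shape)
    t_event = np.maximum(t_event, 0.01)
    u_cens = rng.random(n)
    rate = _solve_censoring_rate(t_event, u_cens, config.admin_horizon, config.censoring_rate)
    t_cens = np.minimum(-np.log(u_cens) / max(rate, 1e-12), config.admin_horizon)
    event = (t_event <= t_cens).astype(int)
    time = np.round(np.where(event == 1, t_event, t_cens), 3)
    outcome = SurvivalOutcome(pd.Series(time, index=samples), pd.Series(event, index=samples))

    # --- split --------------------------------------------------------------
    rng = rngs["split"]
    n_train = int(round(config.train_fraction * n))
    perm = rng.permutation(n)
    labels = np.array(["validation"] * n, dtype=object)
    labels[perm[:n_train]] = "train"
    split = pd.Series(labels, index=samples, name="split")

    gene_lists = generate_prior_gene_lists(config)

    truth = {
        "config": config.to_dict(),
        "subtype": pd.Series(subtype, index=samples),
        "instability_latent": pd.Series(z_instab, index=samples),
        "gii": pd.Series(gii_true, index=samples),
        "linear_predictor": pd.Series(lp, index=samples),
        "module_score": pd.Series(module_score, index=samples),
        "module_genes": module,
        "er_program_genes": er_program,
        "er_gene": er_gene,
        "censoring_rate_solved": float(rate),
    }

    cohort = Cohort(
        expression=expression,
        segments=segments,
        cn_genes=cn_genes,
        clinical=clinical,
        outcome=outcome,
        split=split,
        genes=genes,
        gene_lists=gene_lists,
        truth=truth,
    )
    cohort.validate()
    return cohort


def generate_prior_gene_lists(config: GeneratorConfig, sizes: dict | None = None) -> dict:
    """Synthetic stand-ins for external prior gene lists.

    Returns named gene-id lists mirroring the roles of curated resources:
    ``oncogene_tf`` (oncogenes + transcription factors, the MASP prior),
    ``census_like`` (a cancer-gene-census-style list), ``clustering_like``
    (genes used to define molecular clusters), ``mammaprint_like`` (70-gene
    centroid signature) and ``oncotype_like`` (21 genes with signed weights,
    returned as a dict gene -> weight).  Each list deliberately contains the
    planted prognostic module plus seed-dependent decoys; the planted-module
    membership is identical across seeds, the decoys are not.
    """
    config.validate()
    # default sizes mirror the curated resources they stand in for, clamped
    # to half the gene universe so small desk-scale cohorts stay valid;
    # explicitly requested sizes are never clamped (too-large ones error)
    defaults = {
        "oncogene_tf": 200,
        "census_like": 487,
        "clustering_like": 150,
        "mammaprint_like": 70,
        "oncotype_like": 21,
    }
    half = max(config.n_genes // 2, config.module_size)
    sizes = {
        **{k: min(v, half) for k, v in defaults.items()},
        **(sizes or {}),
    }
    genes = _gene_annotation(config)
    gene_ids = list(genes.index)
    n_sub = min(config.n_subtype_genes, config.n_genes)
    n_er = min(config.n_er_program, config.n_genes - n_sub)
    mod_start = n_sub + n_er
    module = gene_ids[mod_start : mod_start + config.module_size]
    too_big = [k for k, v in sizes.items() if v > config.n_genes]
    if too_big:
        raise ValueError(f"requested list(s) larger than gene universe: {too_big}")
    # decoys drawn from a dedicated child stream (index 6 of the seed spawn,
    # matching generate_cohort's "lists" stream)
    rng = _child_rngs(config.seed, ["subtype", "clinical", "segments", "expression",
                                    "survival", "split", "lists"])["lists"]
    pool = [g for g in gene_ids if g not in module]
    lists = {}
    for name, size in sizes.items():
        planted = module[: min(len(module), size)]
        decoys = list(rng.choice(pool, size=size - len(planted), replace=False))
        members = sorted(planted + decoys)
        if name == "oncotype_like":
            weights = np.round(rng.normal(0.0, 1.0, size=size), 3)
            # planted genes get positive (risk-increasing) weights so the
            # signature tracks the planted hazard direction
            w = dict(zip(members, weights))
            for g in planted:
                w[g] = abs(w[g]) + 0.5
            lists[name] = w
        else:
            lists[name] = members
    return lists
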