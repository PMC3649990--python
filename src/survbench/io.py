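"""Cohort directory format and configuration files.

A cohort is stored as a directory of plain-text tables:

* ``expression.tsv`` / ``cn_genes.tsv`` — genes x samples, first column
  ``gene_id``, header row of sample ids;
* ``segments.seg`` — tab-separated ``sample  chromosome  start  end  logR``
  (1-based inclusive coordinates);
* ``clinical.tsv`` — samples x covariates, first column ``sample``;
* ``outcome.tsv`` — ``sample  time_months  event``;
* ``split.tsv`` — ``sample  split``;
* ``genes.tsv`` — gene annotation ``gene_id  chromosome  start  end``
  (1-based inclusive);
* ``gene_lists.json``, ``config.yaml``, ``truth.json`` — optional extras
  (prior lists, generator config, planted truth for synthetic cohorts).

Round-tripping preserves values and ordering; a sample-roster mismatch
across files is a validation error at read time.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cohort import Cohort, RosterMismatchError, SurvivalOutcome
from .leaderboard import Leaderboard, read_leaderboard, write_leaderboard  # noqa: F401

__all__ = ["write_cohort", "read_cohort", "write_leaderboard", "read_leaderboard"]


def _truth_to_json(truth: dict) -> dict:
    out = {}
    for k, v in truth.items():
        if isinstance(v, pd.Series):
            out[k] = {"__series__": True, "index": list(map(str, v.index)),
                      "values": v.tolist()}
        elif isinstance(v, (np.floating, np.integer)):
            out[k] = v.item()
        else:
            out[k] = v
    return out


def _truth_from_json(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, dict) and v.get("__series__"):
            out[k] = pd.Series(v["values"], index=v["index"])
        else:
            out[k] = v
    return out


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort directory (created if absent)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    cohort.expression.rename_axis("gene_id").to_csv(path / "expression.tsv", sep="\t")
    cohort.cn_genes.rename_axis("gene_id").to_csv(path / "cn_genes.tsv", sep="\t")
    cohort.segments.to_csv(path / "segments.seg", sep="\t", index=False,
                           header=["sample", "chromosome", "start", "end", "logR"])
    cohort.clinical.rename_axis("sample").to_csv(path / "clinical.tsv", sep="\t")
    cohort.outcome.to_frame().rename_axis("sample").to_csv(path / "outcome.tsv", sep="\t")
    cohort.split.rename("split").rename_axis("sample").to_csv(path / "split.tsv", sep="\t")
    if cohort.genes is not None:
        cohort.genes.rename_axis("gene_id").to_csv(path / "genes.tsv", sep="\t")
    if cohort.gene_lists:
        (path / "gene_lists.json").write_text(json.dumps(cohort.gene_lists, indent=1))
    if cohort.truth is not None:
        (path / "truth.json").write_text(json.dumps(_truth_to_json(cohort.truth)))
        if "config" in cohort.truth:
            (path / "config.yaml").write_text(yaml.safe_dump(cohort.truth["config"]))


def read_cohort(path) -> Cohort:
    """Read a cohort directory; validates roster agreement across files."""
    path = Path(path)
    for fname in ["expression.tsv", "cn_genes.tsv", "segments.seg",
                  "clinical.tsv", "outcome.tsv", "split.tsv"]:
        if not (path / fname).exists():
            raise FileNotFoundError(f"cohort directory missing {fname}")

    def matrix(fname):
        # round_trip parsing: written floats must read back bit-identical
        df = pd.read_csv(path / fname, sep="\t", index_col="gene_id",
                         float_precision="round_trip")
        bad = df.columns[~df.apply(lambda c: pd.api.types.is_numeric_dtype(c))]
        if len(bad):
            raise ValueError(f"{fname}: non-numeric matrix cells in columns {list(bad)}")
        return df

    expression = matrix("expression.tsv")
    cn_genes = matrix("cn_genes.tsv")
    segments = pd.read_csv(path / "segments.seg", sep="\t", float_precision="round_trip",
                           dtype={"sample": str, "chromosome": str})
    clinical = pd.read_csv(path / "clinical.tsv", sep="\t", index_col="sample",
                           float_precision="round_trip")
    outcome_df = pd.read_csv(path / "outcome.tsv", sep="\t", index_col="sample",
                             float_precision="round_trip")
    split = pd.read_csv(path / "split.tsv", sep="\t", index_col="sample")["split"]
    genes = None
    if (path / "genes.tsv").exists():
        genes = pd.read_csv(path / "genes.tsv", sep="\t", index_col="gene_id",
                            dtype={"chromosome": str})
    gene_lists = {}
    if (path / "gene_lists.json").exists():
        gene_lists = json.loads((path / "gene_lists.json").read_text())
    truth = None
    if (path / "truth.json").exists():
        truth = _truth_from_json(json.loads((path / "truth.json").read_text()))
    cohort = Cohort(
        expression=expression,
        segments=segments,
        cn_genes=cn_genes,
        clinical=clinical,
        outcome=SurvivalOutcome.from_frame(outcome_df),
        split=split,
        genes=genes,
        gene_lists=gene_lists,
        truth=truth,
    )
    try:
        cohort.validate()
    except RosterMismatchError:
        raise
    return cohort
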