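"""Leaderboard: scored model records with deterministic ordering."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Leaderboard"]

COLUMNS = [
    "model_id", "feature_category", "learner", "concordance_index",
    "n_validation", "timestamp", "provenance",
]


@dataclass
class Leaderboard:
    """Rows of (model_id, category, learner, c-index, ...), unique by model_id.

    Rows are kept sorted by concordance index descending, ties broken by
    model_id lexicographically; failed models carry NaN scores and sort last.
    """

    rows: list = field(default_factory=list)

    def add(self, model_id: str, feature_category: str, learner: str,
            concordance_index: float, n_validation: int,
            timestamp: str = "", provenance: str = "") -> None:
        if any(r["model_id"] == model_id for r in self.rows):
            raise ValueError(f"duplicate model_id {model_id!r}")
        if np.isfinite(concordance_index) and not (0.0 <= concordance_index <= 1.0):
            raise ValueError("concordance_index must lie in [0, 1]")
        self.rows.append({
            "model_id": model_id, "feature_category": feature_category,
            "learner": learner, "concordance_index": float(concordance_index),
            "n_validation": int(n_validation), "timestamp": timestamp,
            "provenance": provenance,
        })

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.rows, columns=COLUMNS)
        return df.sort_values(
            ["concordance_index", "model_id"], ascending=[False, True],
            na_position="last",
        ).reset_index(drop=True)

    def scores(self) -> pd.Series:
        df = self.to_frame()
        return pd.Series(df["concordance_index"].values, index=df["model_id"].values)

    def __len__(self) -> int:
        return len(self.rows)

    def __eq__(self, other) -> bool:
        return isinstance(other, Leaderboard) and self.to_frame().equals(other.to_frame())


def write_leaderboard(board: Leaderboard, path) -> None:
    """Serialize sorted rows as CSV (``.csv``) or JSON (``.json``)."""
    path = Path(path)
    df = board.to_frame()
    if path.suffix == ".json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=1))
    else:
        df.to_csv(path, index=False)


def read_leaderboard(path) -> Leaderboard:
    path = Path(path)
    if path.suffix == ".json":
        records = json.loads(path.read_text())
    else:
        records = pd.read_csv(path, keep_default_na=False).to_dict(orient="records")
    board = Leaderboard()
    for r in records:
        ci = r["concordance_index"]
        ci = float("nan") if ci in ("", None) else float(ci)
        board.add(r["model_id"], r["feature_category"], r["learner"], ci,
                  int(r["n_validation"]), str(r.get("timestamp") or ""),
                  str(r.get("provenance") or ""))
    return board
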